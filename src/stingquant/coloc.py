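"""Per-cell intensity-fraction colocalization and puncta scoring.

The central quantity is a thresholded Manders-type intensity fraction: the
sum of source-channel ("protein A") intensity on pixels where the target
channel ("protein B") exceeds a per-cell percentile threshold, divided by the
total source intensity in the cell. A "puncta mode" variant raises the target
threshold to suppress diffuse target signal when the question is overlap with
target *puncta* rather than with total target signal.

Thresholds are resolved per cell from a shared :class:`~stingquant.image.ThresholdSpec`
so that one setting drives a whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import CellROI, ImageField, ThresholdSpec

__all__ = [
    "ColocMeasurement",
    "PunctaMeasurement",
    "DegenerateCellError",
    "resolve_threshold",
    "coloc_fraction",
    "coloc_fraction_puncta_mode",
    "detect_puncta",
    "puncta_mean_intensity",
    "DEFAULT_COLOC_SPEC",
    "DEFAULT_PUNCTA_SPEC",
]

# Experiment-wide defaults. The percentile and the additive constant are
# analysis settings, not biological constants: they must be held fixed across
# all cells and conditions of one experiment and echoed into outputs.
DEFAULT_COLOC_SPEC = ThresholdSpec(percentile=90.0, offset=0.0)
DEFAULT_PUNCTA_SPEC = ThresholdSpec(percentile=98.0, offset=0.0)


class DegenerateCellError(ValueError):
    """The cell carries zero source intensity — the fraction is undefined."""


@dataclass
class ColocMeasurement:
    cell_id: str
    source_channel: str
    target_channel: str
    fraction: float
    target_threshold: float
    source_floor: float | None = None
    mode: str = "standard"  # "standard" | "puncta"
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")


@dataclass
class PunctaMeasurement:
    cell_id: str
    channel: str
    mean_puncta_intensity: float
    puncta_count: int
    above_threshold_area: int
    threshold: float
    labels: dict = field(default_factory=dict)


def resolve_threshold(
    image: ImageField, roi: CellROI, channel: str, spec: ThresholdSpec
) -> float:
    """Resolve a ThresholdSpec to an absolute intensity within one cell.

    Returns ``percentile(channel pixels inside the ROI, spec.percentile)
    + spec.offset`` with linear interpolation between order statistics.
    """
    mask = roi.mask_for(image.shape)
    return spec.resolve(image.channel(channel)[mask])


def coloc_fraction(
    image: ImageField,
    roi: CellROI,
    source_channel: str,
    target_channel: str,
    target_spec: ThresholdSpec = DEFAULT_COLOC_SPEC,
    source_floor: ThresholdSpec | None = None,
    *,
    _mode: str = "standard",
) -> ColocMeasurement:
    """Fraction of source intensity on above-threshold target pixels.

    numerator   = sum of source intensity over ROI pixels with
                  target >= resolved target threshold (and, when
                  ``source_floor`` is given, source >= resolved floor);
    denominator = sum of source intensity over the ROI (above the floor,
                  when given).

    A cell with zero denominator raises :class:`DegenerateCellError` — such
    cells are excluded and logged, never scored 0.
    """
    mask = roi.mask_for(image.shape)
    src = image.channel(source_channel)
    tgt = image.channel(target_channel)

    t_thr = target_spec.resolve(tgt[mask])
    floor_val: float | None = None
    keep = mask
    if source_floor is not None:
        floor_val = source_floor.resolve(src[mask])
        keep = mask & (src >= floor_val)

    denom = float(src[keep].sum())
    if denom <= 0.0:
        raise DegenerateCellError(
            f"cell {roi.cell_id}: zero total source intensity in ROI"
        )
    num = float(src[keep & (tgt >= t_thr)].sum())
    frac = min(max(num / denom, 0.0), 1.0)
    return ColocMeasurement(
        cell_id=roi.cell_id,
        source_channel=source_channel,
        target_channel=target_channel,
        fraction=frac,
        target_threshold=t_thr,
        source_floor=floor_val,
        mode=_mode,
        labels=dict(roi.labels),
    )


def coloc_fraction_puncta_mode(
    image: ImageField,
    roi: CellROI,
    source_channel: str,
    target_channel: str,
    elevated_spec: ThresholdSpec = DEFAULT_PUNCTA_SPEC,
    source_floor: ThresholdSpec | None = None,
) -> ColocMeasurement:
    """Same fraction with an elevated target threshold.

    Used when the target readout is punctate: the higher percentile
    suppresses diffuse target signal so only overlap with target puncta
    counts. Identical arithmetic to :func:`coloc_fraction`.
    """
    return coloc_fraction(
        image,
        roi,
        source_channel,
        target_channel,
        target_spec=elevated_spec,
        source_floor=source_floor,
        _mode="puncta",
    )


def detect_puncta(
    image: ImageField,
    roi: CellROI,
    channel: str,
    spec: ThresholdSpec = DEFAULT_PUNCTA_SPEC,
    min_area: int = 2,
) -> np.ndarray:
    """Label map of puncta: 8-connected components of above-threshold pixels
    inside the ROI with area >= ``min_area``. Zero puncta is a valid result.
    """
    mask = roi.mask_for(image.shape)
    chan = image.channel(channel)
    thr = spec.resolve(chan[mask])
    fg = mask & (chan >= thr)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    areas = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    out = np.zeros_like(labels)
    nxt = 0
    for i, a in enumerate(areas, start=1):
        if a >= min_area:
            nxt += 1
            out[labels == i] = nxt
    return out


def puncta_mean_intensity(
    image: ImageField,
    roi: CellROI,
    channel: str,
    spec: ThresholdSpec = DEFAULT_PUNCTA_SPEC,
    min_area: int = 2,
    *,
    per_punctum: bool = False,
) -> PunctaMeasurement:
    """Average punctum intensity in one cell.

    Default is pixel-weighted: the mean intensity over all pixels belonging
    to detected puncta. With ``per_punctum=True`` each punctum's mean is
    computed first and the punctum means are averaged. Cells with zero
    puncta score 0 with ``puncta_count=0`` so that untreated controls (which
    legitimately lack puncta) remain on the scale.
    """
    labels = detect_puncta(image, roi, channel, spec, min_area)
    chan = image.channel(channel)
    mask = roi.mask_for(image.shape)
    thr = spec.resolve(chan[mask])
    n = int(labels.max())
    area = int(np.count_nonzero(labels))
    if n == 0:
        mean = 0.0
    elif per_punctum:
        means = ndimage.mean(chan, labels, index=np.arange(1, n + 1))
        mean = float(np.mean(means))
    else:
        mean = float(chan[labels > 0].mean())
    return PunctaMeasurement(
        cell_id=roi.cell_id,
        channel=channel,
        mean_puncta_intensity=mean,
        puncta_count=n,
        above_threshold_area=area,
        threshold=thr,
        labels=dict(roi.labels),
    )
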