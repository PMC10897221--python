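"""Core raster containers: multi-channel image fields, cell ROIs, threshold specs.

Conventions used throughout the package:

* coordinates are 0-based, y-down; a pixel at row ``r``, column ``c`` is the
  unit square centered on the point ``(x=c, y=r)``;
* a polygon ROI covers a pixel iff the pixel's center lies inside the polygon
  (boundary pixels are counted on the low/left side, so an axis-aligned
  rectangle of width ``w`` drawn at integer coordinates covers exactly
  ``w`` pixel columns);
* intensities are non-negative floats; integer TIFF data is converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShPolygon

__all__ = ["ImageField", "CellROI", "ThresholdSpec", "polygon_to_mask"]


class ChannelError(KeyError):
    """Requested channel is not present in the image."""


class EmptyROIError(ValueError):
    """ROI contains no pixels (or lies entirely outside the image)."""


@dataclass
class ImageField:
    """A multi-channel 2-D fluorescence image.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D float array. All channels must
        share one shape.
    pixel_size
        Physical edge length of one pixel (microns), optional metadata.
    bit_depth
        Bit depth of the source data, optional metadata.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(
                f"channel {name!r} not in image (have {self.channel_names})"
            ) from None


def polygon_to_mask(
    polygon: Sequence[Sequence[float]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a simple polygon to a boolean mask under the pixel-center rule.

    ``polygon`` is an ordered list of ``(x, y)`` vertices. A pixel is covered
    iff its center falls inside the polygon; centers exactly on the boundary
    are resolved by nudging the test point by +1e-9 in x and y, which counts
    the low/left edges and excludes the high/right edges.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon must be a list of >= 3 (x, y) vertices")
    poly = _ShPolygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")

    h, w = shape
    # restrict the point-in-polygon test to the polygon's bounding box
    x0 = max(int(np.floor(verts[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(verts[:, 0].max())) + 2, w)
    y0 = max(int(np.floor(verts[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(verts[:, 1].max())) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    inside = shapely.contains_xy(poly, xs.ravel() + 1e-9, ys.ravel() + 1e-9)
    mask[y0:y1, x0:x1] = inside.reshape(ys.shape)
    return mask


@dataclass
class CellROI:
    """One manually annotated cell outline — the unit of quantification.

    Either ``polygon`` (ordered ``(x, y)`` vertex list) or ``mask`` must be
    given; the mask is derived from the polygon lazily when needed.
    """

    cell_id: str
    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    labels: dict = field(default_factory=dict)  # timepoint/condition metadata

    def __post_init__(self) -> None:
        if self.polygon is None and self.mask is None:
            raise ValueError("CellROI needs a polygon or a mask")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def mask_for(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of this ROI on a raster of the given shape."""
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ValueError(
                    f"ROI {self.cell_id}: mask shape {self.mask.shape} != image {shape}"
                )
            m = self.mask
        else:
            m = polygon_to_mask(self.polygon, shape)
        if not m.any():
            raise EmptyROIError(f"ROI {self.cell_id} covers no pixels")
        return m


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-cell percentile threshold, adjusted by an additive constant.

    The threshold for a channel within one cell is::

        percentile(channel pixels inside the cell ROI, percentile) + offset

    with linear interpolation between order statistics. One ThresholdSpec is
    shared across all cells of an experiment; only the resolved intensity
    value varies cell to cell.
    """

    percentile: float = 90.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must be in [0, 100]")

    def resolve(self, pixels: np.ndarray) -> float:
        pixels = np.asarray(pixels, dtype=float).ravel()
        if pixels.size == 0:
            raise EmptyROIError("cannot resolve a threshold on an empty ROI")
        return float(np.percentile(pixels, self.percentile)) + self.offset
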