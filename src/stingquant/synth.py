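"""Synthetic data with known ground truth for every analysis stage.

Four generators emulate the assay readouts quantified by this package:

* two/three-channel cell fields with diffraction-limited vesicle puncta and a
  controllable co-placement fraction (colocalization benchmark);
* DAPI-like nuclear fields mixing smooth elliptical (live) and fragmented,
  multi-lobed (dead) nuclei (viability-counting benchmark);
* ACMA quench traces with valinomycin-initiated exponential decay and a
  CCCP-induced collapse (proton-flux benchmark);
* toy "channels" built from stacked atom rings whose pore radii are known in
  closed form (pore-profiler oracle).

All randomness flows from the explicit seed in each spec; identical spec +
seed gives bit-identical output. Noise (Poisson shot noise followed by
additive Gaussian read noise — the standard camera model) can be switched
off so that noiseless renderings serve as exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coloc import coloc_fraction
from .flux import FluxTrace
from .image import CellROI, ImageField, ThresholdSpec
from .pore import PoreAxis, PoreProfile, SphereFit, StructureModel

__all__ = [
    "PlacementError",
    "ColocSceneSpec",
    "SceneGroundTruth",
    "generate_coloc_image",
    "NucleiSceneSpec",
    "generate_nuclei_image",
    "FluxModelParams",
    "flux_model",
    "generate_flux_trace",
    "ToyChannelSpec",
    "generate_toy_channel",
    "analytic_ring_radius",
]


class PlacementError(RuntimeError):
    """The field is too small to place the requested objects."""


# --------------------------------------------------------------------------
# colocalization scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocSceneSpec:
    """A field of cells with punctate staining in two (or three) channels.

    ``co_placement_fraction`` is the fraction of channel-A puncta that also
    receive a channel-B punctum at the same center; the remaining B puncta
    are placed at independent positions. Puncta within one cell are kept at
    least ``8 * spot_sigma`` apart so spots never overlap (spots are
    truncated at 4 sigma).
    """

    image_size: int = 1024
    n_cells: int = 20
    puncta_per_cell: int = 20
    co_placement_fraction: float = 0.5
    spot_sigma: float = 1.5
    spot_amplitude: float = 500.0
    background_level: float = 100.0
    gaussian_noise_sd: float = 10.0
    poisson_noise: bool = True
    golgi_present: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_placement_fraction <= 1.0:
            raise ValueError("co_placement_fraction must be in [0, 1]")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if self.spot_amplitude < 0 or self.background_level < 0:
            raise ValueError("amplitudes and background must be >= 0")


@dataclass
class SceneGroundTruth:
    """What the generator actually drew, in consumer conventions.

    ``rendered_fraction`` is the mean per-cell intensity-overlap fraction
    computed on the noiseless rendering with the ground-truth thresholds
    (target: percentile 90 + 0.1*amplitude offset; the same spec as a source
    floor, so the punctate source is measured against punctate target — the
    configuration under which rendered tracks designed).
    """

    designed_fraction: float
    rendered_fraction: float
    per_cell_rendered: list[float]
    per_cell_rois: list[CellROI]
    punctum_centers: dict[str, list[np.ndarray]]  # channel -> per-cell (k,2) xy
    threshold_spec: ThresholdSpec = field(default_factory=ThresholdSpec)
    source_floor_spec: ThresholdSpec | None = None


def _disk_polygon(cx: float, cy: float, r: float, n: int = 48) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _render_spots(
    canvas: np.ndarray, centers: np.ndarray, amplitude: float, sigma: float
) -> None:
    """Add isotropic 2-D Gaussian spots truncated at 4 sigma (in place)."""
    h, w = canvas.shape
    rad = int(np.ceil(4.0 * sigma))
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    for cx, cy in centers:
        x0, x1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
        y0, y1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c)
        ys = np.arange(y0c, y1c)
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        r2 = dy2[:, None] + dx2[None, :]
        spot = amplitude * np.exp(-r2 / (2.0 * sigma**2))
        spot[r2 > (4.0 * sigma) ** 2] = 0.0
        canvas[y0c:y1c, x0c:x1c] += spot


def _sample_separated(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    min_sep: float,
    max_tries: int = 200000,
) -> np.ndarray:
    """Uniform points in a disk with pairwise separation >= min_sep."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} puncta with separation {min_sep:.1f} px "
                f"in a disk of radius {radius:.1f} px"
            )
        tries += 1
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0.0, 2.0 * np.pi)
        p = center + np.array([r * np.cos(a), r * np.sin(a)])
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    if not pts:
        return np.empty((0, 2))
    return np.asarray(pts)


def _render_golgi(
    canvas: np.ndarray, rng: np.random.Generator, center: np.ndarray,
    amplitude: float,
) -> None:
    """Elongated, slightly curved ribbon emulating a Golgi apparatus."""
    h, w = canvas.shape
    length = 30.0
    theta = rng.uniform(0.0, np.pi)
    curv = rng.uniform(-0.01, 0.01)
    ts = np.linspace(-length / 2, length / 2, 60)
    xs = center[0] + ts * np.cos(theta) - curv * ts**2 * np.sin(theta)
    ys = center[1] + ts * np.sin(theta) + curv * ts**2 * np.cos(theta)
    _render_spots(canvas, np.column_stack([xs, ys]), amplitude / 6.0, 2.0)


def generate_coloc_image(
    spec: ColocSceneSpec,
) -> tuple[ImageField, SceneGroundTruth]:
    """Render a colocalization scene and its ground truth.

    Channels: ``chA`` (source), ``chB`` (target) and, when requested,
    ``golgi``. Cells are disks on a regular grid; the number of co-placed
    puncta per cell is ``round(f * puncta_per_cell)``. Channel-B extras are
    drawn from a pre-generated per-cell pool so that raising ``f`` with the
    same seed only converts extras into co-placements — this makes the
    rendered fraction monotone in the designed fraction.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n = spec.n_cells

    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    tile_w, tile_h = size / cols, size / rows
    roi_radius = 0.42 * min(tile_w, tile_h)
    margin = 4.0 * spec.spot_sigma + 2.0
    if roi_radius - margin < 2.0 * spec.spot_sigma:
        raise PlacementError(
            f"image_size {size} too small for {n} cells with sigma "
            f"{spec.spot_sigma}"
        )

    shape = (size, size)
    sig_a = np.zeros(shape)
    sig_b = np.zeros(shape)
    sig_g = np.zeros(shape) if spec.golgi_present else None

    n_pp = spec.puncta_per_cell
    k_co = int(round(spec.co_placement_fraction * n_pp))
    min_sep = 8.0 * spec.spot_sigma

    rois: list[CellROI] = []
    centers_a: list[np.ndarray] = []
    centers_b: list[np.ndarray] = []
    for i in range(n):
        r, c = divmod(i, cols)
        cc = np.array([(c + 0.5) * tile_w, (r + 0.5) * tile_h])
        rois.append(
            CellROI(cell_id=f"cell{i:03d}", polygon=_disk_polygon(*cc, roi_radius))
        )
        # one pooled draw: n_pp A positions + n_pp candidate B-extra positions
        pool = _sample_separated(
            rng, 2 * n_pp, cc, roi_radius - margin, min_sep
        )
        a_pos = pool[:n_pp]
        b_pos = np.concatenate([a_pos[:k_co], pool[n_pp : 2 * n_pp - k_co]])
        centers_a.append(a_pos)
        centers_b.append(b_pos)
        _render_spots(sig_a, a_pos, spec.spot_amplitude, spec.spot_sigma)
        _render_spots(sig_b, b_pos, spec.spot_amplitude, spec.spot_sigma)
        if sig_g is not None:
            _render_golgi(sig_g, rng, cc, spec.spot_amplitude)

    channels_clean = {"chA": sig_a + spec.background_level,
                      "chB": sig_b + spec.background_level}
    if sig_g is not None:
        channels_clean["golgi"] = sig_g + spec.background_level
    clean = ImageField(channels={k: v.copy() for k, v in channels_clean.items()})

    # ground-truth intensity-overlap fractions on the noiseless rendering
    gt_spec = ThresholdSpec(percentile=90.0, offset=0.1 * spec.spot_amplitude)
    if n_pp == 0:
        per_cell = [0.0] * len(rois)  # no source signal: nothing to colocalize
    else:
        per_cell = [
            coloc_fraction(
                clean, roi, "chA", "chB", target_spec=gt_spec, source_floor=gt_spec
            ).fraction
            for roi in rois
        ]

    noisy = {}
    for name, arr in channels_clean.items():
        img = arr
        if spec.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.gaussian_noise_sd > 0:
            img = img + rng.normal(0.0, spec.gaussian_noise_sd, size=img.shape)
        noisy[name] = np.clip(img, 0.0, None)

    truth = SceneGroundTruth(
        designed_fraction=spec.co_placement_fraction,
        rendered_fraction=float(np.mean(per_cell)),
        per_cell_rendered=per_cell,
        per_cell_rois=rois,
        punctum_centers={"chA": centers_a, "chB": centers_b},
        threshold_spec=gt_spec,
        source_floor_spec=gt_spec,
    )
    return ImageField(channels=noisy), truth


# --------------------------------------------------------------------------
# nuclear fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleiSceneSpec:
    """A DAPI-like field of live (elliptical) and dead (fragmented) nuclei."""

    n_live: int = 70
    n_dead: int = 30
    live_axis_range: tuple[float, float] = (10.0, 16.0)  # semi-axis, px
    dead_fragmentation: int = 3  # lobes per dead nucleus (2-4)
    amplitude: float = 200.0
    noise_sd: float = 5.0
    image_size: int | None = None  # auto-sized from counts when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise ValueError("counts must be >= 0")
        if self.dead_fragmentation < 2:
            raise ValueError("dead nuclei need >= 2 lobes")


def _ellipse_mask(
    shape: tuple[int, int], center: np.ndarray, a: float, b: float, theta: float
) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - center[0], ys - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_nuclei_image(
    spec: NucleiSceneSpec,
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Render a nuclear field; returns (image, label map, viability list).

    Live nuclei are smooth ellipses (solidity near 1); dead nuclei are
    unions of ``dead_fragmentation`` overlapping small ellipses arranged
    around the nucleus center, giving a concave outline whose solidity falls
    well below the live population. Nuclei sit on a jittered grid and never
    touch. ``labels[i-1]`` gives the viability of object ``i`` in the label
    map.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n_live + spec.n_dead
    if total == 0:
        size = spec.image_size or 64
        return np.zeros((size, size)), np.zeros((size, size), np.int32), []

    tile = 64
    cols = int(np.ceil(np.sqrt(total)))
    rows_n = int(np.ceil(total / cols))
    size = spec.image_size or max(cols, rows_n) * tile
    if spec.image_size is not None:
        tile_fit = size / cols
        if tile_fit < 3.0 * spec.live_axis_range[1]:
            raise PlacementError(
                f"image_size {size} too small for {total} nuclei"
            )
    shape = (size, size)
    tile_w, tile_h = size / cols, size / rows_n

    # shuffle viability over grid positions so dead nuclei are interspersed
    viability = np.array([True] * spec.n_live + [False] * spec.n_dead)
    rng.shuffle(viability)

    labels = np.zeros(shape, dtype=np.int32)
    viable_out: list[bool] = []
    for i in range(total):
        r, c = divmod(i, cols)
        center = np.array(
            [
                (c + 0.5) * tile_w + rng.uniform(-3, 3),
                (r + 0.5) * tile_h + rng.uniform(-3, 3),
            ]
        )
        if viability[i]:
            a = rng.uniform(*spec.live_axis_range)
            b = a * rng.uniform(0.75, 1.0)
            mask = _ellipse_mask(shape, center, a, b, rng.uniform(0, np.pi))
        else:
            # fragmented nucleus: small lobes around an empty center, kept
            # connected by thin chromatin bridges -> one concave object
            k = spec.dead_fragmentation
            mask = np.zeros(shape, dtype=bool)
            base = rng.uniform(0, 2 * np.pi)
            for j in range(k):
                ang = base + 2 * np.pi * j / k + rng.uniform(-0.2, 0.2)
                off = rng.uniform(9.0, 11.0)
                direction = np.array([np.cos(ang), np.sin(ang)])
                lc = center + off * direction
                la = rng.uniform(4.5, 6.0)
                lb = la * rng.uniform(0.8, 1.0)
                mask |= _ellipse_mask(shape, lc, la, lb, ang)
                mask |= _ellipse_mask(
                    shape, center + 0.5 * off * direction, 0.5 * off + 2.0, 2.2, ang
                )
        if (labels[mask] != 0).any():
            raise PlacementError("nuclei overlap; field too crowded")
        labels[mask] = i + 1
        viable_out.append(bool(viability[i]))

    img = np.where(labels > 0, spec.amplitude, 0.0)
    if spec.noise_sd > 0:
        img = np.clip(img + rng.normal(0, spec.noise_sd, shape), 0.0, None)
    return img, labels, viable_out


# --------------------------------------------------------------------------
# ACMA flux traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxModelParams:
    """Piecewise model of an ACMA quench trace.

    Baseline at ``f_baseline`` (1 by construction) until valinomycin;
    exponential quench toward ``f_plateau`` at rate ``k_quench`` until CCCP;
    then exponential collapse toward ``f_min`` at the (fast) rate
    ``k_collapse``. Defaults mirror the assay layout: readings every 20 s,
    valinomycin at ~300 s, CCCP at 1800 s.
    """

    f_baseline: float = 1.0
    k_quench: float = 0.01  # s^-1
    f_plateau: float = 0.5
    t_valinomycin: float = 300.0
    t_cccp: float = 1800.0
    f_min: float = 0.2
    k_collapse: float = 0.05  # s^-1
    noise_sd: float = 0.01
    sample_interval: float = 20.0
    duration: float = 2400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_min <= self.f_plateau <= self.f_baseline:
            raise ValueError("need 0 <= f_min <= f_plateau <= f_baseline")
        if self.k_quench < 0 or self.k_collapse < 0:
            raise ValueError("rate constants must be >= 0")
        if not self.t_valinomycin < self.t_cccp:
            raise ValueError("valinomycin must precede CCCP")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


def flux_model(params: FluxModelParams, t: np.ndarray) -> np.ndarray:
    """Noiseless model fluorescence at times ``t`` (closed form)."""
    t = np.asarray(t, dtype=float)
    f = np.full(t.shape, params.f_baseline)
    mid = (t >= params.t_valinomycin) & (t < params.t_cccp)
    f[mid] = params.f_plateau + (params.f_baseline - params.f_plateau) * np.exp(
        -params.k_quench * (t[mid] - params.t_valinomycin)
    )
    f_at_cccp = params.f_plateau + (
        params.f_baseline - params.f_plateau
    ) * np.exp(-params.k_quench * (params.t_cccp - params.t_valinomycin))
    late = t >= params.t_cccp
    f[late] = params.f_min + (f_at_cccp - params.f_min) * np.exp(
        -params.k_collapse * (t[late] - params.t_cccp)
    )
    return f


def generate_flux_trace(
    params: FluxModelParams, condition: str = "synthetic", replicate: str | int = 0
) -> tuple[FluxTrace, FluxModelParams]:
    """Sample the flux model on a uniform grid, with additive Gaussian noise."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration + 0.5 * params.sample_interval,
                  params.sample_interval)
    f = flux_model(params, t)
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=t.shape)
    trace = FluxTrace(
        times=t,
        fluorescence=f,
        t_valinomycin=params.t_valinomycin,
        t_cccp=params.t_cccp,
        condition=condition,
        replicate=replicate,
        normalized=False,
    )
    return trace, params


# --------------------------------------------------------------------------
# toy channels (pore-profiler oracle)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyChannelSpec:
    """Stacked atom rings with analytically known pore radii.

    Ring ``i`` places ``atoms_per_ring`` atoms uniformly on a circle of
    radius ``ring_center_distances[i]`` in the plane z =
    ``ring_axial_positions[i]``; the largest inscribed sphere at that plane
    sits on the axis with radius ``distance - atom_vdw_radius``. Fewer than
    8 atoms per ring is refused: the gaps between atoms would start to
    dominate the slice geometry.
    """

    ring_axial_positions: tuple[float, ...]
    ring_center_distances: tuple[float, ...]
    atoms_per_ring: int = 12
    atom_vdw_radius: float = 1.7
    element: str = "C"

    def __post_init__(self) -> None:
        if len(self.ring_axial_positions) != len(self.ring_center_distances):
            raise ValueError("one center distance per ring required")
        if self.atoms_per_ring < 8:
            raise ValueError("atoms_per_ring must be >= 8 (gap artifacts)")
        if self.atom_vdw_radius <= 0:
            raise ValueError("atom_vdw_radius must be positive")
        if any(d <= self.atom_vdw_radius for d in self.ring_center_distances):
            raise ValueError(
                "ring_center_distances must exceed atom_vdw_radius (open channel)"
            )


def analytic_ring_radius(spec: ToyChannelSpec, z: float) -> float:
    """On-axis clearance of the toy channel at axial position z (closed form)."""
    zs = np.asarray(spec.ring_axial_positions)
    ds = np.asarray(spec.ring_center_distances)
    return float(np.min(np.sqrt(ds**2 + (z - zs) ** 2)) - spec.atom_vdw_radius)


def generate_toy_channel(
    spec: ToyChannelSpec,
) -> tuple[StructureModel, PoreProfile]:
    """Build the ring-stack structure and its analytic pore profile.

    The analytic profile has one slice per ring, radius
    ``ring_center_distances[i] - atom_vdw_radius``, center on the axis; its
    constriction is the minimum over rings.
    """
    coords = []
    elements = []
    res_ids = []
    chain_ids = []
    m = spec.atoms_per_ring
    for i, (z, d) in enumerate(
        zip(spec.ring_axial_positions, spec.ring_center_distances)
    ):
        ang = 2.0 * np.pi * np.arange(m) / m
        for a in ang:
            coords.append([d * np.cos(a), d * np.sin(a), z])
            elements.append(spec.element)
            res_ids.append(i + 1)
            chain_ids.append("A")
    model = StructureModel(
        coords=np.array(coords),
        elements=elements,
        residue_ids=res_ids,
        chain_ids=chain_ids,
        radii=np.full(len(coords), spec.atom_vdw_radius),
        source="toy-channel",
    )
    axis = PoreAxis(anchor=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0))
    profile = PoreProfile(axis=axis)
    for z, d in sorted(
        zip(spec.ring_axial_positions, spec.ring_center_distances)
    ):
        profile.fits.append(
            SphereFit(
                center=np.array([0.0, 0.0, z]),
                radius=float(d - spec.atom_vdw_radius),
                z=float(z),
            )
        )
    return model, profile
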