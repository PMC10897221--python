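# Methods

This note records the models, parameter choices and numerical conventions
behind each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions that were genuinely open.

## Per-cell thresholded colocalization (`coloc`)

The measurement is an intensity-weighted Manders-type fraction: the sum of
source-channel intensity on pixels where the target channel exceeds a
per-cell threshold, over the total source intensity in the cell. The
threshold is specified as a percentile of the target channel's pixels
within the cell ROI (linear interpolation between closest ranks — the most
common percentile convention, stated explicitly so resolved thresholds are
reproducible) plus an additive offset. One `ThresholdSpec` is shared by all
cells and conditions of an experiment; only its resolved intensity varies
cell to cell.

Defaults: percentile 90 with offset 0 for colocalization, percentile 98
with offset 0 for puncta mode. The percentile and the offset are analysis
settings, not measured constants; they are exposed in every API and CLI
entry point and echoed into output headers. The denominator is the total
source intensity in the cell, read literally from the metric's definition;
an optional source-side floor exists but is off by default. A cell with
zero source intensity raises a degenerate-cell error and is excluded and
logged — scoring it 0 would silently bias condition means.

Puncta are 8-connected components of above-threshold pixels with area ≥
`min_area` (default 2 px, to reject single-pixel shot noise).
"Average punctum intensity" is pixel-weighted by default (mean over all
punctum pixels); a per-punctum-then-average mode is provided because the
two readings are both defensible. Cells with zero puncta score 0 with
`puncta_count = 0`, keeping untreated controls on the measurement scale;
they are flagged by the count rather than dropped. No background
subtraction is applied before quantification.

Coordinates are 0-based, y-down, pixel-centered; a polygon ROI covers a
pixel iff the pixel center falls inside it (boundary resolved to the
low/left side by a 1e-9 nudge), so an axis-aligned w×h rectangle covers
exactly w·h pixels.

Summary statistics are mean ± SEM (sample SD/√n) per group, with unpaired
two-tailed t tests between groups. The default test is Welch (unequal
variances) as the safer choice when group variances are unknown; a
pooled-variance option is provided.

## Live-cell counting from nuclear images (`nuclei`)

Segmentation: Gaussian smoothing (σ = 2 px), global Otsu threshold (fixed
or percentile thresholds selectable), 8-connected components, size filter.
An optional watershed split for touching nuclei exists but is off by
default: the assay uses sparse fields and splitting adds tie-break
sensitivity.

Viability is a shape gate on each segmented nucleus: solidity (area /
convex-hull area), circularity (4πA/P², weighted-steps digital perimeter,
clamped to (0,1]; single-pixel objects get circularity 1 by convention),
and an area window. Defaults: solidity ≥ 0.90, circularity ≥ 0.70, area
50–5000 px. Healthy interphase nuclei are near-elliptical (digital solidity
≳ 0.96); fragmented or multi-lobed nuclei fall well below 0.90. The cutoffs
are configuration, echoed into outputs, since any concrete irregularity
rule is an implementation choice rather than a published constant.
Conservation (viable + excluded = total segmented) holds by construction.

Survival per condition is 100 · mean(live counts) / mean(control live
counts); the SEM is taken over per-replicate percentages computed against
the control mean.

## Pore-radius profiling (`pore`)

At each axial position z the pore radius is the largest sphere inscribable
with its center in the plane normal to the channel axis:
R(z) = max_c min_i(‖c − a_i‖ − r_i). Instead of HOLE's simulated
annealing, the search is deterministic: clearance is evaluated on a coarse
grid (0.25 Å spacing, 15 × 15 Å window centered on the previous slice's
center); a greedy hill climb on the grid graph, started from the warm
start, finds the local maximum *connected to the channel interior* — a
global box maximum would drift into bulk solvent outside the protein; the
winning cell is refined by Nelder–Mead confined to ±1.25 grid spacings.
The refined radius is never below the grid value, a climb that reaches the
window edge marks the slice "open to bulk", and an all-blocked profile
(every R(z) ≤ 0) is reported as a closed channel, not an exception. Slices
advance in 0.5 Å steps; the constriction is the profile minimum with ties
broken toward smaller z.

Van der Waals radii follow the HOLE "simple" set (C 1.85, N 1.75, O 1.65,
S 2.00, H 1.00, P 2.10 Å) by default — the set most likely to match
HOLE-derived published radii — with Bondi radii available for sensitivity
analysis and a 1.80 Å fallback (with warning) for unlisted elements.
Hydrogens are dropped by default since cryo-EM models typically lack them;
heteroatoms are excluded unless requested (profiling the C53-blocked pore
requires including the ligand).

The default axis is the principal axis of the selection's coordinate
covariance through its centroid; (near-)planar selections are rejected with
a request for an explicit two-point override, because their principal axis
lies in the plane and is meaningless as a pore axis. For the STING runs,
`configs/sting_tmd.yaml` records the transmembrane-domain selection
(residues 1–160 of each protomer) as this package's interpretation; since
published profiles do not pin the exact selection or sampling parameters,
agreement with reported constriction radii (≈0.86 Å apo, ≈1.71 Å
cGAMP-bound) is expected within ±0.15 Å rather than exactly. The deposited
structures are not redistributed here; `scripts/fetch_structures.py`
downloads them when network is available, and the corresponding test fails
with an explanatory message until they are present.

Validation rests on analytic ring-stack channels: m atoms evenly spaced on
a circle of radius d enclose an on-axis inscribed sphere of radius
d − r_vdw exactly (moving off-axis strictly decreases the minimal atom
distance), and at an off-ring plane the on-axis clearance is
√(d² + Δz²) − r_vdw. Fewer than 8 atoms per ring is refused, as inter-atom
gaps would start to dominate the slice geometry.

## ACMA flux traces (`flux`)

The assay's published processing has no closed-form description, so the
normalization and metrics here are explicit package choices. Traces are
divided by the mean fluorescence over the pre-valinomycin baseline
(default: all pre-valinomycin samples, ≥ 3 required), making every
downstream quantity invariant to detector gain. Fractional quench is
(1 − F_pre) / (1 − F_min): channel-mediated quench as a fraction of the
full CCCP-defined collapse, with F_pre the mean over the last 60 s before
CCCP (configurable) and F_min the post-CCCP minimum, clamped to [0, 1]
against noise; a trace whose post-CCCP minimum never drops below baseline
is flagged as a failed experiment. Kinetics are fitted as a single
exponential F(t) = f_plateau + (1 − f_plateau)·e^(−k(t − t_val)) on the
valinomycin→CCCP window with bounds k ≥ 0, f_plateau ∈ [0, 1] and a
deterministic log-linear initializer; both the raw normalized curves and
the fit are reported because either may be the readout of interest.
Event times are per-trace metadata (defaulting to ~300 s and 1800 s, the
assay's layout), never hard-coded. Replicates are summarized as pointwise
mean ± SEM on a common grid; mismatched grids are linearly resampled with
a warning, or rejected in strict mode.

## Synthetic data (`synth`)

Generators draw every random quantity from a single explicit seed
(`numpy.random.default_rng`); identical spec + seed gives bit-identical
output.

*Colocalization scenes* place disk-shaped cells on a grid (default 20
cells on a 1024 px field) with diffraction-limited puncta rendered as
isotropic 2-D Gaussians truncated at 4σ (σ = 1.5 px, amplitude 500 over a
background of 100 — signal-to-background 5). Puncta within a cell are kept
≥ 8σ apart so spots never overlap. The designed co-placement fraction f
places round(f · n) channel-B puncta at channel-A centers; the remaining B
puncta come from a pre-generated pool, so raising f with a fixed seed only
converts extras into co-placements and the rendered fraction is monotone
in f. Noise is Poisson on the signal followed by additive Gaussian read
noise (the standard camera model), both switchable off for oracle tests.
The stored ground truth (`rendered_fraction`) is computed on the noiseless
rendering with percentile-90 thresholds offset by 10 % of the spot
amplitude on the target and the same spec as a source floor: with a flat
noiseless background, a pure percentile threshold with zero offset passes
every pixel, and without a source floor the cell's background intensity
dilutes the denominator — this is the configuration under which the
rendered fraction tracks the designed one. Not emulated: 3-D/confocal
stacks, PSF physics, photobleaching, organelle textures; the optional
"Golgi" channel is a curved Gaussian ribbon for layout realism only.

*Nuclear fields* mix smooth ellipses (live; semi-axes 10–16 px) with
fragmented nuclei built from 2–4 small lobes around an empty center,
connected by thin bridges — guaranteeing a concave outline whose solidity
(≲ 0.75) is separated from the live population (≳ 0.96) by the default
0.90 gate. Objects sit on a jittered grid and never touch, matching the
sparse fields of the assay; clumped monolayers are out of scope.

*Flux traces* follow the piecewise model: baseline 1 until valinomycin
(300 s), exponential quench toward f_plateau (default 0.5) at k_quench
(default 0.01 s⁻¹), then exponential collapse toward f_min (0.2) at a fast
k_collapse (0.05 s⁻¹) after CCCP (1800 s), sampled every 20 s with
additive Gaussian noise (σ = 0.01 of baseline).

*Toy channels* stack ≥ 8-atom rings with analytically known slice radii,
serving as the pore profiler's exact oracle.

## Problem sizes and limitations

The validation suite uses 20-cell scenes (one per condition), 30-cell
puncta groups, 100-nucleus fields, 6 flux replicates, and 20 random toy
channels — sizes chosen to match the assays' reported per-panel cell
counts at the small end while keeping the whole suite and the acceptance
script comfortably within a few minutes on one CPU. Passing tests
demonstrate correctness of the quantification arithmetic and robustness to
the modeled camera noise; they cannot certify performance on real
micrographs with uneven illumination, crosstalk, or out-of-focus light,
none of which the generators emulate. The pore profiler assumes a roughly
straight channel: the slice center is optimized in a plane, so strongly
curved pores would need a curved-axis extension.
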