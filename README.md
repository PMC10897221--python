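# stingquant

Quantification toolkit for the assays used to characterize the ion-channel
function of STING (stimulator of interferon genes): ligand-activated STING
opens a proton-conducting pore in its transmembrane domain, deacidifies its
post-Golgi trafficking vesicles, and thereby triggers noncanonical autophagy
(CASM) and cell death. Establishing that chain of evidence rests on four
quantitative readouts, each implemented here as a tested, reusable pipeline
with a synthetic-data generator providing known ground truth:

| readout | module | quantity |
| --- | --- | --- |
| fluorescence colocalization | `stingquant.coloc` | per-cell thresholded intensity fraction (Manders-type M1) |
| puncta formation (lyso-pHluorin, LC3) | `stingquant.coloc` | mean punctum intensity above a percentile threshold |
| cell death | `stingquant.nuclei` | live-nucleus counts with automatic exclusion of irregular (fragmented) nuclei |
| channel geometry | `stingquant.pore` | HOLE-style largest-inscribed-sphere pore-radius profile |
| proton flux in liposomes | `stingquant.flux` | ACMA fractional quench and quench rate constant |

## The core computations

**Intensity-fraction colocalization.** For one manually outlined cell with
source channel A and target channel B, the fraction of A on B is

    f = Σ_{p ∈ ROI, B(p) ≥ τ_B} A(p) / Σ_{p ∈ ROI} A(p)

where the threshold τ_B is a percentile of B's pixels *within that cell*
plus a small additive constant, shared (as a spec, not a value) across all
cells of an experiment. A puncta mode raises the percentile to suppress
diffuse target signal.

**Pore-radius profile.** For a channel structure with atoms a_i of van der
Waals radius r_i and an axis, the pore radius at axial position z is

    R(z) = max_{c ∈ plane(z)} min_i ( ‖c − a_i‖ − r_i )

the largest sphere inscribable at that slice. The profile minimum is the
constriction radius — the number that distinguishes the apo STING
transmembrane domain (~0.86 Å, PDB 6NT5) from the dilated, cGAMP-bound one
(~1.71 Å, PDB 8IK3). The search is a deterministic coarse grid plus
hill-climb and local refinement, validated against analytic ring-stack
channels to 0.01 Å.

**ACMA quench.** Traces are normalized to the pre-valinomycin baseline;
channel-mediated quench is reported as `(1 − F_pre-CCCP) / (1 − F_min
post-CCCP)` and, optionally, as the rate constant of a single-exponential
fit on the valinomycin→CCCP window.

## Worked example

```sh
stingquant simulate --kind coloc --seed 4 --n-cells 4 --out demo
stingquant coloc --image demo/scene.tif --rois demo/rois.json \
    --source ch0 --target ch1 --percentile 90 --offset 50 \
    --source-floor-percentile 90 --out demo/coloc.csv
```

prints

```
wrote coloc scene: designed=0.500 rendered=0.499
quantified 4/4 cells -> demo/coloc.csv
```

`demo/coloc.csv` starts with provenance headers (`# config_hash: ...`,
`# coloc.percentile: 90.0`, ...) followed by one row per cell; the
`fraction` column is the per-cell intensity fraction of channel 0 on
thresholded channel 1 (here ≈ 0.48–0.50 per cell against a designed
co-placement of 0.5 — the residual gap is shot noise on the Poisson camera
model). A pore-profiling example on a toy channel:

```sh
python - <<'PY'
from stingquant import synth
from stingquant.pore import PoreAxis, trace_profile, constriction
model, _ = synth.generate_toy_channel(
    synth.ToyChannelSpec((0., 5., 10.), (5., 3., 5.), 12, 1.7))
profile = trace_profile(model, PoreAxis((0,0,0),(0,0,1)), 0, 10, 0.5)
print(constriction(profile))
PY
```

prints `(5.0, 1.2999999999999996)` — the constriction sits at the middle
ring (z = 5 Å) with radius 3.0 − 1.7 = 1.3 Å, the closed form.

For the real structures, `configs/sting_tmd.yaml` documents the
transmembrane-domain selection and

```sh
stingquant pore --structure data/structures/8ik3.cif --residues 1:160 \
    --radius-set hole-simple --step 0.5 --out results/8ik3_profile.csv
```

writes the radius-vs-z profile and prints the constriction summary.

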