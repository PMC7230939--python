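# muos

Transport simulation and collective-migration analysis for the
**micro-optic-stalk (μOS)** microfluidic device — a two-reservoir,
eight-microchannel chip built to the anatomical scale of the developing
*Drosophila* eye–brain complex. One reservoir stands in for the brain
lobe (BL, the FGF **source**), the other for the eye imaginal disc
(EID, the **sink**), and each 90 µm channel represents one optic-stalk
segment in which retinal neuroblast (RNB) clusters chemotax along the
FGF gradient.

The package is aimed at microfluidics and quantitative cell-migration
researchers who want to (a) predict the concentration fields such a
source–sink device produces, and (b) analyse cluster-tracking data —
or calibrated synthetic stand-ins for it — with the field's standard
trajectory statistics.

## What it computes

**Transport.** Depth-averaged (Hele-Shaw-like) diffusion–advection of
FGF/dextran over the device plan view,

```
∇·(h D ∇C) − ∇·(h u C) = h ∂C/∂t,
```

with thickness `h` (50 µm reservoirs, 10 µm channels), diffusivity
`D = 13.5 µm²/s`, fields normalized to the inlet concentration `C/C₀`,
and a channel Péclet number `Pe = pe_alpha·(R − 1)` modelling the bulk
flow induced by an inlet flow-rate imbalance `R = Q_R/Q_L`. Steady
states are one sparse direct solve; transients use implicit Euler.
From the solution it extracts axial channel profiles, the L/M/H
concentration-region partition of the channel, gradient-linearity R²,
and RMSE against measured profiles.

**Migration metrics.** Per-track total path length `L_T = Σ|Δr|`, net
displacement `D_N = |r(T) − r(0)|`, and the directionality ratio
`DR = Σ cos θ / n`, with θ the angle between each track's
net-displacement vector and the gradient axis; per-size-class
summaries (single cells 1–2, small clusters 3–5, large clusters >5
cells) with mean ± SE.

**Disaggregation.** Fission-event detection from parent-linked tracks
(cell counts conserved), localization of events in the L/M/H regions,
and the timeline of the small-cluster fraction among motile clusters.

**Synthetic experiments.** A seeded Gamma/von-Mises biased random walk
with concentration-gated Poisson fission, calibrated so the per-class
endpoint statistics and the disaggregation timeline match the published
device characterization.

## Worked example

```python
from muos import *

geo = DeviceGeometry()                       # the fabricated dimensions
mask = build_domain_mask(geo, GridSpec(dx=1.0))
field = solve_steady(mask, TransportParams())   # R = 1, balanced inlets
profile = extract_axial_profile(field, 4)       # mid-array channel

print(round(linearity_r2(profile, geo.channel_span), 5))  # 0.99998
print(round(float(profile.at(180.0)), 3))                 # 0.349
for r in partition_regions(profile, geo):
    print(r.label, r.x_span, r.c_range)
# L (150.0, 180.0) (0.034, 0.349)
# M (180.0, 210.0) (0.349, 0.660)
# H (210.0, 240.0) (0.660, 0.965)
```

The balanced-flow gradient is linear across the channel to
R² = 0.99998; the mid-channel concentration is ~0.35 C₀ and the three
channel thirds carry low/medium/high concentration bands overlapping
the reported 0.25–0.40 / 0.40–0.65 / 0.65–0.80 ranges.

```python
exp = generate_tracks(GeneratorConfig(seed=0, n_tracks=500))
print(summarize_by_class(exp.tracks)[
    ["n_tracks", "percent", "lt_mean_um", "dn_mean_um", "dr_mean"]].round(2))
#         n_tracks  percent  lt_mean_um  dn_mean_um  dr_mean
# SINGLE        84     16.8        2.80        0.94    -0.04
# SMALL        301     60.2       17.83        8.86     0.76
# LARGE        115     23.0       14.27        7.24     0.78
```

Small clusters dominate the motile population and show the largest,
most directional migration (L_T ≈ 17.7 µm, DR ≈ 0.72–0.76 toward the
source); single cells jitter below one cell diameter with no
directional bias.

The same stages are scriptable from the shell:

```
muos simulate --ratio 1 --out sim/        # field, profile, regions
muos synth --n 300 --seed 0 --out tracks.csv --truth truth.json
muos analyze --tracks tracks.csv --out analysis/
muos pipeline --seed 0 --out run/         # all stages + checksum manifest
muos sweep-ratio --out sweep.csv          # R² vs flow ratio
```

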