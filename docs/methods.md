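# Methods

## Device geometry and rasterization

The μOS plan view is laid out in continuous µm with the origin at the
outer (left) wall of the EID reservoir and x increasing toward the BL
reservoir: EID spans x ∈ [0, 150], the channel array x ∈ [150, 240],
BL x ∈ [240, 390]; both reservoirs span y ∈ [0, 500]. The EID is the
sink (C/C₀ = 0) and the BL the source (C/C₀ = 1); this follows the
experimental operation of the device (FGF flushed into the right-hand
BL reservoir) and the position axis used for the reported profiles,
which some schematic descriptions of the chip mirror left-to-right.

Channel widths taper linearly from 35 µm at the EID face to 37 µm at
the BL face — only the two end widths are known, so linear
interpolation is the minimal closed assumption. The nominal layout
(eight channels, 35 µm gaps) overfills the 500 µm reservoir face by
41 µm; since the fabricated device does hold eight equally spaced
channels, the builder honours the nominal gap when it fits and
otherwise redistributes the channels with equal gaps (including end
margins) across the face. A `LayoutError` is raised only when the
channels themselves cannot fit. The reservoir:array volume ratio
quoted for the design (50:1) does not follow from the stated
dimensions (the actual ratio is ≈260:1 per reservoir against the
channel array volume); nothing downstream uses it.

Rasters are cell-centered with square cells (default dx = 1 µm, which
resolves the 35 µm channels with 35 cells across); a cell belongs to a
region if its center does. Channel plan areas converge to the analytic
trapezoid areas as dx → 0 and the mask build is deterministic.

## Transport model

Transport is depth-averaged (Hele-Shaw) diffusion–advection with
thickness-weighted fluxes, ∇·(hD∇C) − ∇·(huC) = h∂C/∂t. The step from
50 µm reservoirs to 10 µm channels is the dominant geometric effect
and enters through h. All fields are normalized to the inlet
concentration C₀ = 100 ng/mL; absolute concentrations appear only in
I/O metadata.

**Diffusivity.** D = 13.5 µm²/s (1.35 × 10⁻¹¹ m²/s), the free
diffusivity of a ~22 kDa protein such as FGF-8. The corresponding
diffusion time across a 90 µm channel, L²/2D ≈ 5 min, matches the
minutes-scale gradient development observed in the device, which is
the strongest internal consistency check on the units. Configurable.

**Boundary conditions.** Both reservoirs are flushed continuously at
~1 µL/min against a reservoir volume of ~0.004 µL — roughly half a
reservoir volume per second — so the solved model pins *every wall
face of the reservoir cells* at the corresponding inlet concentration
(`bc_mode="flushed"`, the default). Channel walls are zero-flux. The
alternative `bc_mode="outer"` pins only the two outermost walls; it
yields nearly identical steady profiles across the channel (mid-channel
0.386 vs 0.349) but its transient is limited by diffusive charging of
the reservoirs (~40 min to 95% of steady), which contradicts the
observed minutes-scale development; the flushed default gives ≈ 525 s.
The outlet port and the Y-shaped loading channels are not part of the
solved domain — their effect is absorbed into these inlet conditions.

**Advection at off-balance flow.** An inlet flow-rate imbalance
R = Q_R/Q_L ≠ 1 drives a small bulk flow along the channels. It is
modelled as a uniform axial velocity confined to the channels with
channel Péclet number Pe = pe_alpha·(R − 1), directed from source to
sink for R > 1. `pe_alpha = 0.8` was calibrated once so that the R = 2
profile's linearity lands inside the reported 0.94–0.99 R² band
(measured: R² = 0.988 at R = 2, 0.956 at R = 3, 0.9998 at R = 1); it
is a config parameter, not a fitted physical constant. A full
Navier–Stokes velocity field is deliberately out of scope; the printed
fluid properties (ρ = 1070 kg/m³, μ = 1.05, with the viscosity unit as
printed likely mPa·s rather than Pa·s) are carried as metadata only.

**Discretization.** Cell-centered finite volumes: harmonic-mean face
conductances h_f D/dx (exact for the h-step at channel mouths),
central advective face fluxes (cell Péclet ≲ 0.03 ≪ 2 everywhere, so
the scheme is monotone in practice), ghost-cell Dirichlet faces at
half-cell distance. Steady states are solved by sparse LU
(~1.8 × 10⁵ unknowns at dx = 1, ~1 s); a disconnected domain or a
relative residual above 10⁻¹⁰ raises `SolverError`. Transients use
implicit Euler with one reused LU factorization; the scheme is
conservative, and the per-step ledger (change in Σ h C dx² vs net
boundary influx) agrees to machine precision. Verified against the 1D
closed forms on a straight channel (linear for u = 0; C(x) =
(e^{Pe·x/L} − 1)/(e^{Pe} − 1) for u ≠ 0) to < 0.1% and for grid
convergence (mid-channel value moves 0.4% from dx = 1 to dx = 0.5).

**Profiles and regions.** Axial profiles are width-averages over a
channel's y-band, extended across both reservoirs. The channel span
[150, 240] is partitioned positionally into thirds — L [150, 180],
M [180, 210], H [210, 240] µm — with each region's C/C₀ range taken
from the profile; under default conditions these land at
(0.03–0.35), (0.35–0.66) and (0.66–0.97), overlapping the reported
0.25–0.40 / 0.40–0.65 / 0.65–0.80 bands. The reported ranges imply a
larger share of the drop inside the reservoirs than the flushed model
produces; the region *structure* (linear gradient split into thirds,
H-boundary near C/C₀ ≈ 0.65) is reproduced.

## Migration metrics

L_T is the sum of per-frame Euclidean steps, D_N the first-to-last
distance, so L_T ≥ D_N by the triangle inequality. DR uses one angle
per trajectory, from the net-displacement vector, because the
directionality sum is defined per RNB; tracks with D_N = 0 have no
angle and are excluded but counted (`n_stationary`). A whole track's
size class is the mode of its per-frame classes with ties broken
toward the larger class; per-frame classes remain available for
timeline analysis. SE denominators are track counts per class. Class
summaries are computed in canonical track-id order so they are exactly
order-invariant.

## Disaggregation analysis

Fission events are reconstructed from parent links: children sharing a
parent and a birth frame form one event, located at the parent's
position at that frame; child sizes must sum to the parent's size
there (`ConservationError` otherwise). The timeline statistic is the
fraction of *motile* clusters whose current size is 3–5 cells; motile
means the lineage path length — the track's own path plus its
ancestors' up to each birth — exceeds 4 µm (one cell diameter), the
scale below which single cells are described as non-migratory. Lineage
inheritance matters: a cluster that just detached from a moving parent
is itself moving. A parent is counted up to, but not at, its fission
frame, where its children replace it.

## Synthetic-experiment generator

The generator emulates the study conditions: nine frames at 60 min
intervals (t = 0…8 h), class mix 16/65/21% (renormalized from the
printed percentages, which sum to 102), and cluster sizes drawn
uniformly from 1–2 / 3–5 / 6–8 cells per class. Each frame advances a
track by a Gamma step (shape 4, i.e. CV = 0.5 — moderate step-length
variability) in a von Mises direction about +x.

**Calibration.** Step means are the published per-class L_T divided by
8 steps (single 0.334, small 2.2125, large 1.775 µm/frame). The
angular concentrations are found by root-finding on pilot simulations
of the published per-class DR — the analytic mean-resultant-length
relation A(κ) = I₁(κ)/I₀(κ) describes single steps, not the
net-displacement angle of an 8-step walk, so pilot simulation is the
authority. Calibrated defaults: κ = 0 (single), 0.817 (small), 0.980
(large). Net displacement is emergent rather than fitted: small
clusters land at D_N ≈ 8.6–8.9 µm (published 10.1 ± 0.99, within
2 SE), but the single-κ walk cannot simultaneously reproduce the large
clusters' low D_N/L_T ratio (0.31) and high DR (0.79) — their
simulated D_N sits at the upper edge of the published 2 SE band. This
is a known limitation of the walk model, not of the metrics.

**Fission.** Clusters of more than 5 cells split as a Poisson process
with per-hour hazard gated by the local axial concentration: zero
wherever C/C₀ ≥ 0.65 (the lower bound of the H region). The hazard for
a frame interval is evaluated at the position where the cluster is
next observed — the same position the split is localized at — so the
no-fission zone coincides exactly with the gate and no events can fall
in the H region. Children partition the parent uniformly at random
into parts of ≥ 3 cells whenever possible (parts below 3 only when the
parent size forces them); splits on the last transition are suppressed
because their children would be single-point tracks. For the
disaggregation experiment the initial small/large mix and the hazard
are calibrated to the two published timeline anchors (42% small at
2 h, 65% at 8 h): a closed-form inversion of the one-shot fission
model f(t) = (a + 2(1 − e^{−λt}))/(a + 2 − e^{−λt}) gives the starting
point, and three pilot-simulation corrections account for the motility
threshold and concentration gating the closed form ignores. The
calibrated process also reproduces the intermediate published points
(51% at 4 h, 59% at 6 h) without being fitted to them.

**Determinism.** All randomness descends from one seed through a
`SeedSequence` spawn tree (one branch per track, sub-branches per
fission child), so runs are bit-reproducible and track streams are
independent of each other.

**What the generator does not emulate.** Wall interactions (tracks are
unconfined), cluster aggregation/merging, en-masse migration kinetics,
spatially varying motility, adhesion-molecule mechanisms, and any
step-level kinematics of real RNBs — the walk is a statistical
stand-in constrained only by endpoint summaries. Passing
parameter-recovery tests therefore demonstrates that the *analysis
stages* are correct and unbiased at realistic sample sizes, not that
real RNB kinematics follow a Gamma/von-Mises walk.

## Numerical and interface choices

* Intensity-profile emulation adds i.i.d. Gaussian noise to the clean
  width-averaged profile and clips to [0, 1]; RMSE of noisy vs clean
  recovers the noise SD.
* A constant profile is treated as degenerately linear (R² = 1);
  a window with fewer than 3 samples or constant x raises.
* Track CSVs carry units in the header names; ImageJ Manual-Tracking
  imports require explicit pixel size and frame interval because the
  exports are uncalibrated, and receive a user-supplied default
  cluster size (the plugin records none).
* Problem sizes used by the reproduction script — dx = 1 µm for the
  transport solve, 500 tracks for the directionality ensemble, 25
  replicates of 300 clusters for the timeline — keep every statistic's
  replicate-to-replicate spread well inside the published error bars
  while running in seconds on one CPU.
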