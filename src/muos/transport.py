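"""Depth-averaged scalar transport in the μOS device.

The device is thin compared with its plan-view extent, so transport of
FGF (or the FITC-dextran tracer used to validate it) is modelled as
depth-averaged (Hele-Shaw-like) diffusion with thickness-weighted
fluxes,

    ∇·(h D ∇C) − ∇·(h u C) = h ∂C/∂t,

where ``h`` is the local device height (50 µm in the reservoirs, 10 µm
in the channels).  The source (BL) side is continuously flushed with
reagent at ``C/C0 = 1`` and the sink (EID) side with plain medium at
``C/C0 = 0``; all fields are reported normalized to the inlet
concentration ``C0``.

At equal inlet flow rates (R = Q_R/Q_L = 1) the channels carry no bulk
flow and each develops a linear steady gradient.  Imbalanced flushing
(R ≠ 1) drives a small bulk velocity along the channels, modelled as a
uniform axial velocity with channel Péclet number
``Pe = pe_alpha · (R − 1)``; ``pe_alpha`` is calibrated once against
the reported linearity band of the off-balance gradients (see
docs/methods.md).

Discretization is a cell-centered finite-volume scheme: harmonic-mean
face conductances ``h_f D / dx``, central (second-order) advective face
fluxes — the cell Péclet number is ≪ 1 everywhere, so the scheme is
monotone in practice — and ghost-cell Dirichlet faces.  Steady states
come from one sparse direct solve; transients use implicit Euler with a
reused LU factorization.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy import stats

from .geometry import DomainMask, DeviceGeometry, EID, BL, CHANNEL0

__all__ = [
    "TransportParams",
    "ConcentrationField",
    "AxialProfile",
    "GradientRegions",
    "GradientRegion",
    "TransientResult",
    "SolverError",
    "solve_steady",
    "solve_transient",
    "time_to_steady_fraction",
    "extract_axial_profile",
    "partition_regions",
    "linearity_r2",
    "rmse",
]


class SolverError(RuntimeError):
    """Singular/disconnected domain or a non-converged solve."""


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the transport model.

    The diffusivity default (13.5 µm²/s) is the free diffusivity of a
    ~22 kDa protein such as FGF-8; with the 90 µm channel length it
    gives the minutes-scale gradient development seen in the device.
    ``rho`` and ``mu`` are carried as metadata only — the depth-averaged
    model needs no momentum solve.
    """

    D: float = 13.5           # diffusivity, µm²/s
    C0: float = 100.0         # inlet concentration, ng/mL (metadata; fields are C/C0)
    QL: float = 1.0           # left (sink) inlet flow rate, µL/min
    QR: float = 1.0           # right (source) inlet flow rate, µL/min
    pe_alpha: float = 0.8     # channel Péclet per unit flow-ratio imbalance
    rho: float = 1070.0       # density, kg/m³ (metadata)
    mu: float = 1.05          # viscosity (metadata; units as printed upstream)
    bc_mode: str = "flushed"  # "flushed": all non-array reservoir walls pinned;
                              # "outer": only the two outer walls pinned
    u_channel: Optional[float] = None  # explicit axial channel velocity µm/s (overrides pe_alpha)

    def __post_init__(self) -> None:
        for name in ("D", "C0", "QL", "QR"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.bc_mode not in ("flushed", "outer"):
            raise ValueError(f"unknown bc_mode {self.bc_mode!r}")

    @property
    def R(self) -> float:
        """Flow-rate ratio Q_R/Q_L of source to sink inlets."""
        return self.QR / self.QL

    def channel_peclet(self) -> float:
        return self.pe_alpha * (self.R - 1.0)

    def channel_velocity(self, channel_length: float) -> float:
        """Axial bulk velocity in the channels, µm/s (>0 toward the BL).

        R > 1 pushes excess source-side flow through the channels toward
        the sink, i.e. in the −x direction.
        """
        if self.u_channel is not None:
            return self.u_channel
        return -self.channel_peclet() * self.D / channel_length


@dataclass(frozen=True)
class ConcentrationField:
    """Normalized concentration ``C/C0`` raster over a domain mask."""

    values: np.ndarray        # float [ny, nx]; 0 outside the mask
    mask: DomainMask
    params: TransportParams

    def __post_init__(self) -> None:
        inside = self.mask.inside
        v = self.values[inside]
        if v.size and (v.min() < -1e-6 or v.max() > 1.0 + 1e-6):
            raise ValueError(
                f"C/C0 out of [0, 1] inside the domain: [{v.min():.3g}, {v.max():.3g}]"
            )

    def sample(self, x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray:
        """Bilinear sample of C/C0 at (x, y) µm, clipped to the raster."""
        dx = self.mask.dx
        ny, nx = self.mask.shape
        fi = np.clip(np.asarray(x, dtype=float) / dx - 0.5, 0.0, nx - 1.0)
        fj = np.clip(np.asarray(y, dtype=float) / dx - 0.5, 0.0, ny - 1.0)
        i0 = np.clip(np.floor(fi).astype(int), 0, nx - 2)
        j0 = np.clip(np.floor(fj).astype(int), 0, ny - 2)
        wx, wy = fi - i0, fj - j0
        v = self.values
        return ((1 - wx) * (1 - wy) * v[j0, i0] + wx * (1 - wy) * v[j0, i0 + 1]
                + (1 - wx) * wy * v[j0 + 1, i0] + wx * wy * v[j0 + 1, i0 + 1])


@dataclass(frozen=True)
class AxialProfile:
    """Width-averaged C/C0 along a channel axis, extended into both reservoirs."""

    x: np.ndarray  # µm from the EID outer wall, strictly increasing
    c: np.ndarray  # C/C0

    def __post_init__(self) -> None:
        if len(self.x) != len(self.c):
            raise ValueError("x and c must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    def at(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.interp(x, self.x, self.c)


@dataclass(frozen=True)
class GradientRegion:
    label: str                    # "L", "M" or "H"
    x_span: tuple[float, float]   # µm
    c_range: tuple[float, float]  # (min, max) C/C0 within the span


@dataclass(frozen=True)
class GradientRegions:
    """The low/medium/high concentration thirds of the channel span."""

    L: GradientRegion
    M: GradientRegion
    H: GradientRegion

    def __iter__(self):
        return iter((self.L, self.M, self.H))

    def locate(self, x: float) -> str:
        """Region label for an axial position; 'OUTSIDE' beyond the channel."""
        for region in self:
            lo, hi = region.x_span
            if lo <= x <= hi:
                return region.label
        return "OUTSIDE"


# ----------------------------------------------------------------------
# discretization
# ----------------------------------------------------------------------

def _cell_velocity(mask: DomainMask, params: TransportParams) -> np.ndarray:
    u = np.zeros(mask.shape)
    x0, x1 = mask.channel_span
    uval = params.channel_velocity(x1 - x0)
    if uval != 0.0:
        u[mask.labels >= CHANNEL0] = uval
    return u


def _dirichlet_faces(mask: DomainMask, params: TransportParams,
                     c_left: float, c_right: float):
    """Return (j, i, side, value) arrays of Dirichlet boundary faces.

    side: 0=W, 1=E, 2=S, 3=N.  The left/right extreme columns of the
    wetted domain are always pinned (the flushed inlet walls).  In
    "flushed" mode every other wall face of a reservoir cell is pinned
    at that reservoir's inlet value too — continuous flushing holds the
    reservoir perimeter at the inlet concentration — except the faces
    looking toward the channel array.
    """
    inside = mask.inside
    ny, nx = inside.shape
    cols = np.where(inside.any(axis=0))[0]
    i_min, i_max = cols[0], cols[-1]

    jj, ii, ss, vv = [], [], [], []

    j = np.where(inside[:, i_min])[0]
    jj.append(j); ii.append(np.full_like(j, i_min)); ss.append(np.zeros_like(j)); vv.append(np.full(j.shape, c_left))
    j = np.where(inside[:, i_max])[0]
    jj.append(j); ii.append(np.full_like(j, i_max)); ss.append(np.ones_like(j)); vv.append(np.full(j.shape, c_right))

    if params.bc_mode == "flushed":
        pad = np.zeros((ny + 2, nx + 2), dtype=bool)
        pad[1:-1, 1:-1] = inside
        wall_w = inside & ~pad[1:-1, :-2]
        wall_e = inside & ~pad[1:-1, 2:]
        wall_s = inside & ~pad[:-2, 1:-1]
        wall_n = inside & ~pad[2:, 1:-1]
        # drop the extreme columns already pinned above
        for arr in (wall_w, wall_e, wall_s, wall_n):
            arr[:, i_min] = False
            arr[:, i_max] = False
        for res_label, value in ((EID, c_left), (BL, c_right)):
            res = mask.labels == res_label
            for side, wall in enumerate((wall_w, wall_e, wall_s, wall_n)):
                j, i = np.where(wall & res)
                jj.append(j); ii.append(i)
                ss.append(np.full_like(j, side)); vv.append(np.full(j.shape, value))

    return (np.concatenate(jj), np.concatenate(ii),
            np.concatenate(ss), np.concatenate(vv))


def _assemble(mask: DomainMask, params: TransportParams,
              c_left: float, c_right: float):
    """Build the steady operator ``A C = b`` over inside cells.

    The balance for each cell is written per unit plan area (divided by
    dx²), so the transient capacity coefficient is simply the local
    thickness ``h``.  Returns (A, b, index-map, capacity).
    """
    inside = mask.inside
    dx = mask.dx
    D = params.D
    ny, nx = inside.shape
    N = int(inside.sum())
    if N == 0:
        raise SolverError("empty domain")
    index = -np.ones((ny, nx), dtype=np.int64)
    index[inside] = np.arange(N)
    h = mask.thickness
    u = _cell_velocity(mask, params)

    rows, cols, vals = [], [], []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    # interior faces, x then y
    for axis, is_x in ((1, True), (0, False)):
        sl_a = (slice(None), slice(0, -1)) if is_x else (slice(0, -1), slice(None))
        sl_b = (slice(None), slice(1, None)) if is_x else (slice(1, None), slice(None))
        both = inside[sl_a] & inside[sl_b]
        ja, ia = np.where(both)
        if is_x:
            a_idx = index[ja, ia]; b_idx = index[ja, ia + 1]
            ha, hb = h[ja, ia], h[ja, ia + 1]
            uf = 0.5 * (u[ja, ia] + u[ja, ia + 1])
        else:
            a_idx = index[ja, ia]; b_idx = index[ja + 1, ia]
            ha, hb = h[ja, ia], h[ja + 1, ia]
            uf = 0.0
        hf = 2.0 * ha * hb / (ha + hb)
        g = D * hf / dx**2
        add(a_idx, a_idx, g); add(a_idx, b_idx, -g)
        add(b_idx, b_idx, g); add(b_idx, a_idx, -g)
        if is_x and np.any(uf != 0.0):
            # central advective flux u_f h_f (C_a + C_b)/2 through the face,
            # positive toward +x; per-area contribution /dx
            a = uf * hf / (2.0 * dx)
            add(a_idx, a_idx, a); add(a_idx, b_idx, a)
            add(b_idx, a_idx, -a); add(b_idx, b_idx, -a)

    # Dirichlet boundary faces (ghost at half-cell distance)
    jd, idd, sd, vd = _dirichlet_faces(mask, params, c_left, c_right)
    r = index[jd, idd]
    g = 2.0 * D * h[jd, idd] / dx**2
    add(r, r, g)
    np.add.at(b, r, g * vd)
    # advective boundary flux with the face held at the Dirichlet value
    ub = u[jd, idd]
    x_faces = sd < 2
    if np.any((ub != 0.0) & x_faces):
        sgn = np.where(sd == 1, 1.0, -1.0)  # outward normal in x
        adv = np.where(x_faces, sgn * ub * h[jd, idd] / dx, 0.0)
        np.add.at(b, r, -adv * vd)

    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )

    # every wetted cell must be able to see a Dirichlet face
    adj = sparse.csr_matrix(
        (np.ones(len(np.concatenate(rows))), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    ncomp, comp = connected_components(adj, directed=False)
    pinned = np.zeros(N, dtype=bool)
    pinned[r] = True
    for c in range(ncomp):
        if not pinned[comp == c].any():
            raise SolverError(
                "domain contains a region disconnected from every inlet wall"
            )

    capacity = h[inside]
    return A, b, index, capacity


def _field_from_vector(vec: np.ndarray, mask: DomainMask,
                       params: TransportParams) -> ConcentrationField:
    # round roundoff-level overshoots back into [0, 1]; anything larger is a
    # genuine maximum-principle violation and is left for the field validator
    if vec.size and vec.min() >= -1e-9 and vec.max() <= 1.0 + 1e-9:
        vec = np.clip(vec, 0.0, 1.0)
    values = np.zeros(mask.shape)
    values[mask.inside] = vec
    return ConcentrationField(values=values, mask=mask, params=params)


def solve_steady(mask: DomainMask, params: TransportParams | None = None,
                 c_left: float = 0.0, c_right: float = 1.0,
                 tol: float = 1e-10) -> ConcentrationField:
    """Steady-state C/C0 field for the given domain and parameters.

    ``c_left``/``c_right`` are the normalized inlet concentrations held
    on the EID (sink) and BL (source) walls.  Raises
    :class:`SolverError` on a disconnected domain or if the residual of
    the direct solve exceeds ``tol`` (relative).
    """
    params = params or TransportParams()
    A, b, index, _ = _assemble(mask, params, c_left, c_right)
    try:
        lu = splu(A.tocsc())
        c = lu.solve(b)
    except RuntimeError as exc:  # singular factorization
        raise SolverError(f"steady solve failed: {exc}") from exc
    if not np.all(np.isfinite(c)):
        raise SolverError("steady solve produced non-finite values")
    ref = np.linalg.norm(b) if np.linalg.norm(b) > 0 else 1.0
    residual = np.linalg.norm(A @ c - b) / ref
    if residual > tol:
        raise SolverError(f"steady residual {residual:.3e} exceeds tol {tol:.3e}")
    return _field_from_vector(c, mask, params)


@dataclass
class TransientResult:
    """Implicit-Euler time series with a per-step mass ledger.

    ``mass_change[k]`` is the change in total dissolved amount
    (Σ h·C·dx²) over step k and ``boundary_influx[k]`` the net influx
    through the Dirichlet walls over the same step; the two agree to
    solver precision because the scheme is conservative.
    """

    times: np.ndarray
    fields: list[ConcentrationField]
    mass_change: np.ndarray
    boundary_influx: np.ndarray


def solve_transient(mask: DomainMask, params: TransportParams | None = None,
                    t_end: float = 600.0, dt: float = 1.0,
                    field0: Optional[ConcentrationField] = None,
                    c_left: float = 0.0, c_right: float = 1.0,
                    store_every: int = 1) -> TransientResult:
    """Integrate the transient transport equation to ``t_end`` seconds.

    Implicit Euler: unconditionally stable, so ``dt`` controls accuracy
    only.  ``field0`` defaults to C = 0 everywhere (reagent first
    admitted at t = 0).  Stored fields are subsampled every
    ``store_every`` steps (the initial and final states always kept).
    """
    params = params or TransportParams()
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    A, b, index, cap = _assemble(mask, params, c_left, c_right)
    N = A.shape[0]
    c = np.zeros(N) if field0 is None else field0.values[mask.inside].astype(float).copy()

    M = sparse.diags(cap / dt)
    lu = splu((M + A).tocsc())
    n_steps = int(np.ceil(t_end / dt - 1e-12))
    dx2 = mask.dx**2

    times = [0.0]
    fields = [_field_from_vector(c.copy(), mask, params)]
    dmass, influx = [], []
    mass = float(np.sum(cap * c)) * dx2
    for step in range(1, n_steps + 1):
        c = lu.solve(M @ c + b)
        if not np.all(np.isfinite(c)):
            raise SolverError(f"non-finite values at step {step} (t={step * dt:.3g}s)")
        new_mass = float(np.sum(cap * c)) * dx2
        # net Dirichlet influx at the new time level equals b - (A c) acting
        # through boundary terms; for the interior-conservative scheme the
        # whole residual of the steady operator is the boundary exchange
        dmass.append(new_mass - mass)
        influx.append(float(np.sum(b - A @ c)) * dx2 * dt)
        mass = new_mass
        if step % store_every == 0 or step == n_steps:
            times.append(step * dt)
            fields.append(_field_from_vector(c.copy(), mask, params))
    return TransientResult(
        times=np.asarray(times),
        fields=fields,
        mass_change=np.asarray(dmass),
        boundary_influx=np.asarray(influx),
    )


def _midchannel_probe(mask: DomainMask) -> tuple[np.ndarray, np.ndarray]:
    """Cells of the middle channel at the axial midpoint column."""
    x0, x1 = mask.channel_span
    xm = 0.5 * (x0 + x1)
    i = int(np.clip(round(xm / mask.dx - 0.5), 0, mask.shape[1] - 1))
    k = mask.n_channels // 2
    ch = mask.channel_cells(k)
    j = np.where(ch[:, i])[0]
    if j.size == 0:
        raise SolverError("mid-channel probe column contains no channel cells")
    return j, np.full_like(j, i)


def time_to_steady_fraction(mask: DomainMask, params: TransportParams | None = None,
                            fraction: float = 0.95, dt: float = 2.0,
                            t_max: float = 6000.0,
                            c_left: float = 0.0, c_right: float = 1.0) -> float:
    """Time (s) for the channel-midpoint C/C0 to reach ``fraction`` of steady.

    Starts from C = 0 everywhere and integrates with implicit Euler
    (reused factorization) until the width-averaged midpoint value of
    the middle channel crosses the target; the crossing is located by
    linear interpolation between steps.
    """
    params = params or TransportParams()
    steady = solve_steady(mask, params, c_left=c_left, c_right=c_right)
    j, i = _midchannel_probe(mask)
    target = fraction * float(steady.values[j, i].mean())

    A, b, index, cap = _assemble(mask, params, c_left, c_right)
    c = np.zeros(A.shape[0])
    M = sparse.diags(cap / dt)
    lu = splu((M + A).tocsc())
    probe_idx = index[j, i]

    prev_val, prev_t = 0.0, 0.0
    t = 0.0
    while t < t_max:
        c = lu.solve(M @ c + b)
        t += dt
        val = float(c[probe_idx].mean())
        if val >= target:
            if val == prev_val:
                return t
            return prev_t + dt * (target - prev_val) / (val - prev_val)
        prev_val, prev_t = val, t
    raise SolverError(f"midpoint did not reach {fraction:.0%} of steady within {t_max}s")


def boundary_wall_fluxes(field: ConcentrationField,
                         c_left: float = 0.0, c_right: float = 1.0) -> dict[str, float]:
    """Net influx (amount/s, µm³·C0-units) through the sink and source walls.

    Positive values are flow *into* the device.  At steady state the
    source-side influx balances the sink-side outflux.
    """
    mask, params = field.mask, field.params
    dx = mask.dx
    h = mask.thickness
    u = _cell_velocity(mask, params)
    jd, idd, sd, vd = _dirichlet_faces(mask, params, c_left, c_right)
    ci = field.values[jd, idd]
    flux = 2.0 * params.D * h[jd, idd] * (vd - ci)  # diffusive, per face
    x_faces = sd < 2
    sgn = np.where(sd == 1, 1.0, -1.0)
    flux = flux - np.where(x_faces, sgn * u[jd, idd] * h[jd, idd] * vd * dx, 0.0)
    is_source = vd == c_right
    return {
        "sink": float(flux[~is_source].sum()),
        "source": float(flux[is_source].sum()),
    }


# ----------------------------------------------------------------------
# profiles, regions and fit statistics
# ----------------------------------------------------------------------

def extract_axial_profile(field: ConcentrationField, channel_index: int) -> AxialProfile:
    """Width-averaged C/C0 along one channel, extended across the reservoirs.

    For each raster column the values are averaged over the wetted cells
    within the channel's y-band (the band of its widest section), which
    inside the channel is exactly the channel width-average and inside
    the reservoirs is the band continuation of the channel centerline.
    """
    mask = field.mask
    if not 0 <= channel_index < mask.n_channels:
        raise IndexError(
            f"channel index {channel_index} out of range [0, {mask.n_channels})"
        )
    ch = mask.channel_cells(channel_index)
    jrows = np.where(ch.any(axis=1))[0]
    band = np.zeros(mask.shape, dtype=bool)
    band[jrows, :] = True
    band &= mask.inside
    counts = band.sum(axis=0)
    cols = counts > 0
    sums = np.where(band, field.values, 0.0).sum(axis=0)
    x = mask.x_centers[cols]
    c = sums[cols] / counts[cols]
    return AxialProfile(x=x, c=c)


def partition_regions(profile: AxialProfile, geometry: DeviceGeometry) -> GradientRegions:
    """Split the channel span into the L/M/H concentration thirds.

    The low (L), medium (M) and high (H) regions are the EID-side,
    central and BL-side thirds of the channel; each record carries the
    min/max of the profile within its span.
    """
    x0, x1 = geometry.channel_span
    if profile.x[0] > x0 + 1e-9 or profile.x[-1] < x1 - 1e-9:
        raise ValueError(
            f"profile [{profile.x[0]}, {profile.x[-1]}] does not cover the channel span [{x0}, {x1}]"
        )
    edges = np.linspace(x0, x1, 4)
    regions = []
    for label, lo, hi in zip("LMH", edges[:-1], edges[1:]):
        xs = np.linspace(lo, hi, 301)
        cs = profile.at(xs)
        regions.append(GradientRegion(label=label, x_span=(float(lo), float(hi)),
                                      c_range=(float(np.min(cs)), float(np.max(cs)))))
    return GradientRegions(*regions)


def linearity_r2(profile: AxialProfile, x_window: tuple[float, float]) -> float:
    """Ordinary-least-squares R² of C/C0 vs x within ``x_window``."""
    lo, hi = x_window
    sel = (profile.x >= lo - 1e-9) & (profile.x <= hi + 1e-9)
    x, c = profile.x[sel], profile.c[sel]
    if x.size < 3:
        raise ValueError(f"need >=3 samples in window [{lo}, {hi}], got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate window: constant x")
    if np.allclose(c, c[0]):
        return 1.0  # a constant profile is exactly (degenerately) linear
    fit = stats.linregress(x, c)
    return float(fit.rvalue**2)


def rmse(simulated: np.ndarray, measured: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length sequences."""
    sim = np.asarray(simulated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if sim.shape != mea.shape:
        raise ValueError(f"length mismatch: {sim.shape} vs {mea.shape}")
    if sim.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((sim - mea) ** 2)))
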