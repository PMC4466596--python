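"""Steady-state potential landscape of the rule module.

The stochastic gating dynamics dS/dt = F(S) + sqrt(2D) xi(t), with
D = (sigma_rule/2)^2 per second, define a Fokker-Planck equation

    dP/dt = -div(F P) + D lap(P)

whose steady state P_ss yields a generalized potential through the
Boltzmann relation U = -ln P_ss.  The rule module does not satisfy
detailed balance, so U is a *generalized* potential (the steady state
also carries a divergence-free flux, which is not computed here), but
its minima, basins and barriers quantify the stability of the
spontaneous and rule attractors.

The equation is integrated on a uniform (S1, S2) grid with an implicit
backward-in-time, centered-in-space (BTCS) scheme and absorbing
boundaries (P = 0), starting from a homogeneous density, until the
density change per unit time drops below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .rule import RuleParams, _drift_arrays, compute_effective_couplings, diffusion_coefficient

__all__ = [
    "FPGrid",
    "PotentialLandscape",
    "drift_field",
    "fp_operator",
    "fp_steady_state",
    "potential_from_pss",
]

DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class FPGrid:
    """Uniform grid over the unit square of gating variables."""

    n: int = 128
    lo: float = 0.0
    hi: float = 1.0

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def h(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)

    @property
    def cell_area(self) -> float:
        return self.h * self.h


@dataclass
class PotentialLandscape:
    """Gridded steady-state density and Boltzmann potential."""

    grid: FPGrid
    Pss: np.ndarray  # (n, n), indexed [i_S1, j_S2], normalized sum*h^2 = 1
    U: np.ndarray | None
    D_diff: float  # diffusion coefficient (1/s)
    params: RuleParams
    n_iter: int = 0
    converged: bool = False
    residual: float = np.nan

    @property
    def s1_axis(self) -> np.ndarray:
        return self.grid.axis

    @property
    def s2_axis(self) -> np.ndarray:
        return self.grid.axis


def drift_field(params: RuleParams, grid: FPGrid):
    """Noise-free drift (1/s) of both gating variables on the grid nodes.

    Landscapes are input-free: the selective inputs I1, I2 are zero, as
    when reconstructing attractor stability between trials.
    """
    cp = compute_effective_couplings(params)
    s = grid.axis
    S1, S2 = np.meshgrid(s, s, indexing="ij")
    d1, d2, _, _ = _drift_arrays(S1, S2, cp)
    return d1 * 1000.0, d2 * 1000.0  # ms^-1 -> s^-1


def _bernoulli(w: np.ndarray) -> np.ndarray:
    """B(w) = w / (exp(w) - 1), the exponential-fitting weight (B(0)=1)."""
    w = np.asarray(w, dtype=float)
    small = np.abs(w) < 1e-12
    big = w > 500.0
    safe = np.where(small | big, 1.0, w)
    out = np.where(small, 1.0, safe / np.expm1(safe))
    return np.where(big, 0.0, out)


def fp_operator(
    params: RuleParams,
    grid: FPGrid = FPGrid(),
    dt: float = 0.01,
    boundary: str = "absorbing",
):
    """Assemble the implicit update matrix on the interior nodes.

    The probability flux J = F P - D grad(P) is discretized in
    conservative flux form with exponentially fitted (Scharfetter-
    Gummel) face weights: across the face between nodes k and k+1 with
    face velocity u and Peclet number w = u h / D,

        J = (D/h) * [B(-w) P_k - B(w) P_(k+1)],   B(w) = w/(e^w - 1),

    which reduces to the centered-in-space stencil for |w| << 1 and
    remains positivity-preserving in the drift-dominated regime the
    rule module operates in (|w| up to a few hundred).  Backward-in-
    time (implicit Euler) stepping then gives A P_next = P_current with
    A = I - dt*L.

    Returns (A, interior_shape); boundary values are fixed at 0 and
    excluded from the system.  Interior nodes are ordered row-major
    over (S1, S2).

    ``boundary="absorbing"`` fixes P = 0 on the outermost nodes (flux
    leaks out and the density is renormalized each step).
    ``boundary="reflecting"`` imposes zero flux through the domain
    edges instead, matching trajectory simulations in which the gating
    variables are clamped to [0, 1].
    """
    if boundary not in ("absorbing", "reflecting"):
        raise ValueError("boundary must be 'absorbing' or 'reflecting'")
    n = grid.n
    h = grid.h
    D = diffusion_coefficient(params.sigma_rule, per="s")
    if D <= 0:
        raise ValueError("sigma_rule must be nonzero for a landscape")
    F1, F2 = drift_field(params, grid)

    m = n - 2
    # face velocities between interior nodes (and to the zero boundary)
    # x-faces: (n-1, n) between rows i and i+1; y-faces analogous
    ux = 0.5 * (F1[:-1, :] + F1[1:, :])  # (n-1, n)
    uy = 0.5 * (F2[:, :-1] + F2[:, 1:])  # (n, n-1)
    wx = ux * h / D
    wy = uy * h / D
    Bx_m = _bernoulli(-wx)  # weight on the lower-index node
    Bx_p = _bernoulli(wx)  # weight on the higher-index node
    By_m = _bernoulli(-wy)
    By_p = _bernoulli(wy)

    g = D / h**2
    I, J = np.meshgrid(np.arange(1, n - 1), np.arange(1, n - 1), indexing="ij")
    k = (I - 1) * m + (J - 1)

    # dP_ij/dt gains g*B(w_east)*P_east etc.; diagonal loses outflow
    east = g * Bx_p[I, J]  # from node (i+1, j) through face i+1/2
    west = g * Bx_m[I - 1, J]  # from node (i-1, j) through face i-1/2
    north = g * By_p[I, J]  # from node (i, j+1) through face j+1/2
    south = g * By_m[I, J - 1]
    loss_e = Bx_m[I, J].copy()
    loss_w = Bx_p[I - 1, J].copy()
    loss_n = By_m[I, J].copy()
    loss_s = By_p[I, J - 1].copy()
    if boundary == "reflecting":
        # no flux through faces adjacent to the domain edge
        loss_e[I == n - 2] = 0.0
        loss_w[I == 1] = 0.0
        loss_n[J == n - 2] = 0.0
        loss_s[J == 1] = 0.0
    diag = -g * (loss_e + loss_w + loss_n + loss_s)

    rows = [k.ravel()]
    cols = [k.ravel()]
    vals = [1.0 - dt * diag.ravel()]

    inner = I < n - 2  # neighbor (i+1, j) is interior
    rows.append(k[inner])
    cols.append((k + m)[inner])
    vals.append(-dt * east[inner])
    inner = I > 1
    rows.append(k[inner])
    cols.append((k - m)[inner])
    vals.append(-dt * west[inner])
    inner = J < n - 2
    rows.append(k[inner])
    cols.append((k + 1)[inner])
    vals.append(-dt * north[inner])
    inner = J > 1
    rows.append(k[inner])
    cols.append((k - 1)[inner])
    vals.append(-dt * south[inner])

    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m * m, m * m),
    )
    return A, (m, m)


def fp_steady_state(
    params: RuleParams,
    grid: FPGrid = FPGrid(),
    dt: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 5000,
    compute_potential: bool = True,
    boundary: str = "absorbing",
) -> PotentialLandscape:
    """Propagate a homogeneous density to its steady state.

    Each implicit step solves the linear system and renormalizes the
    density; iteration stops at the relative residual criterion
    max|P_next - P| / (dt * max P) < tol.  The implicit scheme is
    unconditionally stable, so ``dt`` (seconds) is chosen for
    convergence speed rather than accuracy of the transient; 1 s steps
    resolve the steady state while skipping the slow metastable
    transient.  Raises if the residual does not reach tolerance within
    ``max_iter`` steps.
    """
    if dt <= 0 or tol <= 0:
        raise ValueError("dt and tol must be positive")
    p = params.canonical()
    A, (m, _) = fp_operator(p, grid, dt, boundary=boundary)
    try:
        lu = splu(A)
    except RuntimeError as exc:  # pragma: no cover
        raise RuntimeError(f"singular Fokker-Planck system: {exc}") from exc

    area = grid.cell_area
    P = np.full(m * m, 1.0)
    P /= P.sum() * area
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        P_next = lu.solve(P)
        P_next = np.maximum(P_next, 0.0)
        P_next /= P_next.sum() * area
        resid = float(np.max(np.abs(P_next - P)) / (dt * max(P_next.max(), 1e-300)))
        P = P_next
        if resid < tol:
            break
    converged = resid < tol
    if not converged:
        raise RuntimeError(
            f"Fokker-Planck iteration did not converge: residual {resid:.3e} "
            f"after {it} steps (tol {tol:.1e})"
        )

    full = np.zeros((grid.n, grid.n))
    full[1:-1, 1:-1] = P.reshape(m, m)
    full /= full.sum() * area
    land = PotentialLandscape(
        grid=grid,
        Pss=full,
        U=None,
        D_diff=diffusion_coefficient(p.sigma_rule, per="s"),
        params=p,
        n_iter=it,
        converged=converged,
        residual=resid,
    )
    if compute_potential:
        land.U = potential_from_pss(land)
    return land


def potential_from_pss(landscape: PotentialLandscape, floor: float = DENSITY_FLOOR):
    """Boltzmann potential U = -ln(P_ss), shifted so its minimum is 0."""
    U = -np.log(np.maximum(landscape.Pss, floor))
    return U - U.min()


def local_maxima(P: np.ndarray, threshold_frac: float = 1e-12):
    """Grid indices of strict local maxima above a fraction of the peak."""
    n1, n2 = P.shape
    peaks = []
    thr = P.max() * threshold_frac
    core = P[1:-1, 1:-1]
    mask = (
        (core > P[:-2, 1:-1])
        & (core > P[2:, 1:-1])
        & (core > P[1:-1, :-2])
        & (core > P[1:-1, 2:])
        & (core > P[:-2, :-2])
        & (core > P[2:, 2:])
        & (core > P[:-2, 2:])
        & (core > P[2:, :-2])
        & (core > thr)
    )
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii + 1, jj + 1):
        peaks.append((int(i), int(j)))
    peaks.sort(key=lambda t: -P[t])
    return peaks


def save_landscape(landscape: PotentialLandscape, path) -> None:
    """Write axes, density, potential and metadata to an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("s1_axis", data=landscape.s1_axis)
        f.create_dataset("s2_axis", data=landscape.s2_axis)
        f.create_dataset("Pss", data=landscape.Pss)
        if landscape.U is not None:
            f.create_dataset("U", data=landscape.U)
        f.attrs["D_diff"] = landscape.D_diff
        f.attrs["s_NMDA"] = landscape.params.s_NMDA
        f.attrs["s_GABA"] = landscape.params.s_GABA
        f.attrs["sigma_rule"] = landscape.params.sigma_rule
        f.attrs["n_iter"] = landscape.n_iter
        f.attrs["converged"] = landscape.converged
        f.attrs["residual"] = landscape.residual


def load_landscape(path) -> PotentialLandscape:
    import h5py

    with h5py.File(path, "r") as f:
        Pss = f["Pss"][()]
        U = f["U"][()] if "U" in f else None
        grid = FPGrid(n=Pss.shape[0])
        params = RuleParams(
            s_NMDA=float(f.attrs["s_NMDA"]),
            s_GABA=float(f.attrs["s_GABA"]),
            sigma_rule=float(f.attrs["sigma_rule"]),
        )
        return PotentialLandscape(
            grid=grid,
            Pss=Pss,
            U=U,
            D_diff=float(f.attrs["D_diff"]),
            params=params,
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
            residual=float(f.attrs["residual"]),
        )
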