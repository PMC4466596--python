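"""Minimal-action transition paths between the two rule attractors.

In the weak-noise (path-integral) picture, the probability of a
spontaneous transition between attractors is dominated by the path of
minimal action.  Working in the Hamilton-Jacobi framework removes the
explicit time dependence: along a path x(l) parameterized by arc
length,

    S = integral [ sqrt((E_eff + V(x)) / D) - F_l / (2 D) ] dl

with the effective potential V = |F|^2 / (4 D) + div(F) / 2, the
tangential drift F_l = F . dl/|dl|, and the energy-like constant
E_eff, chosen as -min V so the transition takes the longest kinetic
time t = integral dl / (2 sqrt(D (E_eff + V))).

The action is discretized on 50 line elements whose endpoints are the
two rule minima of the potential landscape; interior nodes are
optimized by quasi-Newton descent with a penalty of 1e5 on the
variance of element lengths (the penalty regularizes the
parameterization and is excluded from the reported action).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .landscape import PotentialLandscape, drift_field, local_maxima
from .rule import RuleParams, _drift_arrays, compute_effective_couplings, diffusion_coefficient

__all__ = [
    "TransitionPath",
    "ActionResult",
    "effective_potential_V",
    "hj_action",
    "minimize_path_action",
]


@dataclass
class TransitionPath:
    """Ordered (S1, S2) nodes of a discretized transition path."""

    nodes: np.ndarray  # (n_nodes, 2)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass
class ActionResult:
    """Minimal action for one transition direction."""

    action: float
    path: TransitionPath
    E_eff: float
    converged: bool
    kinetic_time: float
    n_clipped: int = 0  # midpoints where E_eff + V < 0 was clipped to 0


def _drift_at(points: np.ndarray, couplings) -> np.ndarray:
    """Drift F (1/s) at arbitrary (S1, S2) points, shape (n, 2)."""
    d1, d2, _, _ = _drift_arrays(points[..., 0], points[..., 1], couplings)
    return np.stack([d1, d2], axis=-1) * 1000.0


def effective_potential_V(
    points, params: RuleParams, h: float = 1e-5, couplings=None
) -> np.ndarray:
    """V = |F|^2/(4D) + div(F)/2 at the given points (1/s).

    The divergence is evaluated by central differences with step ``h``
    in each gating coordinate.
    """
    p = params.canonical()
    D = diffusion_coefficient(p.sigma_rule, per="s")
    if D <= 0:
        raise ValueError("sigma_rule must be nonzero")
    cp = couplings if couplings is not None else compute_effective_couplings(p)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    F = _drift_at(pts, cp)
    ex = np.array([h, 0.0])
    ey = np.array([0.0, h])
    dFx = (_drift_at(pts + ex, cp)[:, 0] - _drift_at(pts - ex, cp)[:, 0]) / (2 * h)
    dFy = (_drift_at(pts + ey, cp)[:, 1] - _drift_at(pts - ey, cp)[:, 1]) / (2 * h)
    V = (F[:, 0] ** 2 + F[:, 1] ** 2) / (4.0 * D) + 0.5 * (dFx + dFy)
    return V if np.asarray(points).ndim > 1 else float(V[0])


def hj_action(
    path: TransitionPath | np.ndarray,
    params: RuleParams,
    E_eff: float,
    couplings=None,
    return_clipped: bool = False,
):
    """Discretized Hamilton-Jacobi action of a path (penalty excluded).

    Midpoint rule per line element:
    sum [ sqrt((E_eff + V)/D) - F_l/(2D) ] * dl, with negative
    (E_eff + V) values (discretization noise near the minima) clipped
    to zero.
    """
    nodes = path.nodes if isinstance(path, TransitionPath) else np.asarray(path)
    p = params.canonical()
    D = diffusion_coefficient(p.sigma_rule, per="s")
    cp = couplings if couplings is not None else compute_effective_couplings(p)
    seg = np.diff(nodes, axis=0)
    dl = np.linalg.norm(seg, axis=1)
    ok = dl > 0
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    V = effective_potential_V(mid, p, couplings=cp)
    F = _drift_at(mid, cp)
    with np.errstate(invalid="ignore", divide="ignore"):
        F_l = np.where(ok, (F * seg).sum(axis=1) / np.where(ok, dl, 1.0), 0.0)
    EV = E_eff + V
    n_clipped = int(np.sum(EV < 0))
    EV = np.maximum(EV, 0.0)
    S = float(np.sum((np.sqrt(EV / D) - F_l / (2.0 * D)) * dl))
    if return_clipped:
        return S, n_clipped
    return S


def _kinetic_time(nodes, params, E_eff, couplings) -> float:
    p = params.canonical()
    D = diffusion_coefficient(p.sigma_rule, per="s")
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    dl = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    EV = np.maximum(E_eff + effective_potential_V(mid, p, couplings=couplings), 1e-12)
    return float(np.sum(dl / (2.0 * np.sqrt(D * EV))))


def _rule_minima(landscape: PotentialLandscape, params: RuleParams | None = None):
    """(S1, S2) of the rule-1 and rule-2 minima of U and the spontaneous one.

    Endpoints come from the landscape's potential minima; if the density
    is so concentrated that one rule basin falls below floating-point
    resolution (very small sigma_rule), the noise-free stable fixed
    points stand in, which coincide with the basin minima in that limit.
    """
    ax = landscape.grid.axis
    peaks = local_maxima(landscape.Pss)
    pts = [(ax[i], ax[j]) for i, j in peaks]
    rule1 = max((p for p in pts if p[0] > p[1]), default=None, key=lambda p: p[0] - p[1])
    rule2 = max((p for p in pts if p[1] > p[0]), default=None, key=lambda p: p[1] - p[0])
    spont = min(pts, key=lambda p: abs(p[0] - p[1])) if pts else None
    if rule1 is None or rule2 is None:
        if params is None:
            raise ValueError("landscape does not show two rule basins")
        import warnings

        from .rule import find_fixed_points

        warnings.warn(
            "rule basins not resolved in the steady-state density; "
            "falling back to noise-free fixed points as path endpoints",
            stacklevel=3,
        )
        stable = [f for f in find_fixed_points(params) if f[4]]
        asym = sorted(
            [f[:2] for f in stable if abs(f[0] - f[1]) > 1e-3], key=lambda p: -p[0]
        )
        sym = [f[:2] for f in stable if abs(f[0] - f[1]) <= 1e-3]
        if len(asym) != 2:
            raise ValueError("no pair of rule attractors found")
        rule1, rule2 = asym
        spont = sym[0] if sym else None
    if spont is not None and abs(spont[0] - spont[1]) > 0.05:
        spont = None  # no distinct spontaneous peak
    return np.array(rule1), np.array(rule2), (np.array(spont) if spont is not None else None)


def _initial_paths(a, b, via, n_nodes):
    t = np.linspace(0.0, 1.0, n_nodes)[:, None]
    straight = a + t * (b - a)
    inits = [straight]
    if via is not None:
        half = n_nodes // 2 + 1
        t1 = np.linspace(0.0, 1.0, half)[:, None]
        leg1 = a + t1 * (via - a)
        t2 = np.linspace(0.0, 1.0, n_nodes - half + 1)[:, None]
        leg2 = via + t2 * (b - via)
        inits.append(np.vstack([leg1, leg2[1:]]))
    return inits


def minimize_path_action(
    params: RuleParams,
    landscape: PotentialLandscape,
    n_elements: int = 50,
    penalty: float = 1e5,
    max_iter: int = 5000,
) -> dict:
    """Minimal action between the rule attractors, both directions.

    Endpoints are the rule-1 and rule-2 minima of the landscape's
    potential; E_eff = -min V over the landscape grid.  Interior nodes
    are optimized by L-BFGS from two initializations (straight line,
    and a polyline through the spontaneous minimum when present); the
    lower-action solution is reported per direction.

    Returns ``{"1to2": ActionResult, "2to1": ActionResult}``.
    """
    p = params.canonical()
    cp = compute_effective_couplings(p)
    rule1, rule2, spont = _rule_minima(landscape, p)

    # E_eff from the grid minimum of V (interior nodes; the boundary
    # cells of the landscape carry the absorbing condition, not dynamics)
    ax = landscape.grid.axis
    S1g, S2g = np.meshgrid(ax[1:-1], ax[1:-1], indexing="ij")
    pts = np.stack([S1g.ravel(), S2g.ravel()], axis=1)
    Vg = effective_potential_V(pts, p, couplings=cp)
    E_eff = -float(np.min(Vg))

    n_nodes = n_elements + 1
    results = {}
    for key, (a, b) in {"1to2": (rule1, rule2), "2to1": (rule2, rule1)}.items():
        best = None
        for init in _initial_paths(a, b, spont, n_nodes):
            x0 = init[1:-1].ravel()

            def objective(x):
                nodes = np.vstack([a, x.reshape(-1, 2), b])
                S = hj_action(nodes, p, E_eff, couplings=cp)
                dl = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
                return S + penalty * float(np.var(dl))

            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "maxfun": 10 * max_iter},
            )
            nodes = np.vstack([a, res.x.reshape(-1, 2), b])
            S, n_clip = hj_action(nodes, p, E_eff, couplings=cp, return_clipped=True)
            cand = (S, nodes, bool(res.success), n_clip)
            if best is None or cand[0] < best[0]:
                best = cand
        S, nodes, ok, n_clip = best
        results[key] = ActionResult(
            action=S,
            path=TransitionPath(nodes),
            E_eff=E_eff,
            converged=ok,
            kinetic_time=_kinetic_time(nodes, p, E_eff, cp),
            n_clipped=n_clip,
        )
    return results
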