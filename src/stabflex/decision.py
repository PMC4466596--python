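"""Three-dimensional nonlinear drift-diffusion model of four-choice decisions.

A winner-take-all network of four stimulus-selective excitatory pools
sharing one inhibitory pool, expanded at the bifurcation where the
spontaneous state loses stability, reduces to three amplitude equations
on the null-space coordinates ``(X, Y, Z)``:

    tau dX/dt = alpha/2 * (dI1 - dI2) + beta*X*Z + In_X
    tau dY/dt = alpha/2 * (dI3 - dI4) - beta*Y*Z + In_Y
    tau dZ/dt = alpha/4 * (dI1 + dI2 - dI3 - dI4) + beta/4 * (X^2 - Y^2) + In_Z

with ``tau = tau_NMDA`` = 100 ms.  The four single-population activity
directions form a symmetric tetrahedron in this space; projecting the
state back onto them yields per-pool activity increments, and the first
projection to cross a 10 Hz threshold determines choice and reaction
time.  The nonlinearity makes trajectories diverge in finite time, so
the exact threshold value barely affects the reaction times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionParams",
    "DecisionState",
    "DriftInputs",
    "decision_drift",
    "project_populations",
    "simulate_decision",
]

TAU_DECISION = 100.0  # ms, tau_NMDA
TAU_NOISE = 2.0  # ms, tau_AMPA of the OU noise


@dataclass(frozen=True)
class DecisionParams:
    """Effective parameters of the reduced decision module.

    ``alpha`` scales external inputs (fixed at 1; any overall scale is
    absorbed by the fitted drift parameters), ``beta`` the quadratic
    winner-take-all term, ``sigma_decision`` the OU noise amplitude
    (canonicalized by absolute value), ``c_plus`` the feed-forward
    rule-to-decision weight and ``threshold`` the decision bound on the
    population projections (10 Hz-equivalent units).
    """

    beta: float
    sigma_decision: float
    c_plus: float
    alpha: float = 1.0
    threshold: float = 10.0
    tau: float = TAU_DECISION

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def canonical(self) -> "DecisionParams":
        return DecisionParams(
            beta=self.beta,
            sigma_decision=abs(self.sigma_decision),
            c_plus=self.c_plus,
            alpha=self.alpha,
            threshold=self.threshold,
            tau=self.tau,
        )


@dataclass
class DecisionState:
    X: float = 0.0
    Y: float = 0.0
    Z: float = 0.0
    Inoise_X: float = 0.0
    Inoise_Y: float = 0.0
    Inoise_Z: float = 0.0
    t: float = 0.0


@dataclass(frozen=True)
class DriftInputs:
    """Per-population input increments during stimulus presentation."""

    dI1: float = 0.0
    dI2: float = 0.0
    dI3: float = 0.0
    dI4: float = 0.0


def decision_drift(
    state: DecisionState, params: DecisionParams, inputs: DriftInputs
) -> tuple[float, float, float]:
    """Deterministic time derivatives (dX/dt, dY/dt, dZ/dt) in 1/ms."""
    p = params
    a, b, tau = p.alpha, p.beta, p.tau
    dX = (a * 0.5 * (inputs.dI1 - inputs.dI2) + b * state.X * state.Z + state.Inoise_X) / tau
    dY = (a * 0.5 * (inputs.dI3 - inputs.dI4) - b * state.Y * state.Z + state.Inoise_Y) / tau
    dZ = (
        a * 0.25 * (inputs.dI1 + inputs.dI2 - inputs.dI3 - inputs.dI4)
        + b * 0.25 * (state.X**2 - state.Y**2)
        + state.Inoise_Z
    ) / tau
    return dX, dY, dZ


def project_populations(state) -> tuple[float, float, float, float]:
    """Project (X, Y, Z) onto the four population-increase directions.

    p1 = X/2 + Z/2, p2 = -X/2 + Z/2, p3 = Y/2 - Z/2, p4 = -Y/2 - Z/2;
    the projections always sum to zero.
    """
    X, Y, Z = (state.X, state.Y, state.Z) if isinstance(state, DecisionState) else state
    return (
        0.5 * X + 0.5 * Z,
        -0.5 * X + 0.5 * Z,
        0.5 * Y - 0.5 * Z,
        -0.5 * Y - 0.5 * Z,
    )


def simulate_decision(
    params: DecisionParams,
    stimulus_inputs: DriftInputs | tuple[float, float, float, float],
    rule_rate_feed=None,
    stim_window: tuple[float, float] = (0.0, 900.0),
    trial_duration: float = 2000.0,
    dt: float = 0.5,
    rng_seed: int | None = None,
    record_trajectory: bool = False,
):
    """Simulate one decision trial; return (decision, rt, trajectory).

    ``stimulus_inputs`` holds the stimulus-driven components (D terms)
    of the four input increments; ``rule_rate_feed``, if given, is a
    callable ``t -> (r1, r2)`` adding the feed-forward rule input
    ``c_plus * r1`` to pools 1-2 and ``c_plus * r2`` to pools 3-4.  All
    inputs act only during the stimulus window.  ``decision`` is 1-4 for
    the first projection crossing the threshold, or 0 if none crosses
    before trial end (rt is then nan).
    """
    if dt > 1.0:
        raise ValueError("dt must be <= 1 ms")
    p = params.canonical()
    if isinstance(stimulus_inputs, DriftInputs):
        D = (stimulus_inputs.dI1, stimulus_inputs.dI2, stimulus_inputs.dI3, stimulus_inputs.dI4)
    else:
        D = tuple(float(v) for v in stimulus_inputs)

    rng = np.random.default_rng(rng_seed)
    sd_ss = p.sigma_decision / math.sqrt(2.0)
    decay = math.exp(-dt / TAU_NOISE)
    kick = sd_ss * math.sqrt(1.0 - decay * decay)

    n_steps = int(round(trial_duration / dt))
    X = Y = Z = 0.0
    nX = nY = nZ = 0.0
    traj = [] if record_trajectory else None
    decision, rt = 0, math.nan
    for i in range(n_steps):
        t = i * dt
        stim_on = stim_window[0] <= t < stim_window[1]
        if stim_on:
            r1, r2 = rule_rate_feed(t) if rule_rate_feed is not None else (0.0, 0.0)
            dI1 = D[0] + p.c_plus * r1
            dI2 = D[1] + p.c_plus * r1
            dI3 = D[2] + p.c_plus * r2
            dI4 = D[3] + p.c_plus * r2
        else:
            dI1 = dI2 = dI3 = dI4 = 0.0
        dX = (p.alpha * 0.5 * (dI1 - dI2) + p.beta * X * Z + nX) / p.tau
        dY = (p.alpha * 0.5 * (dI3 - dI4) - p.beta * Y * Z + nY) / p.tau
        dZ = (
            p.alpha * 0.25 * (dI1 + dI2 - dI3 - dI4)
            + p.beta * 0.25 * (X * X - Y * Y)
            + nZ
        ) / p.tau
        X += dX * dt
        Y += dY * dt
        Z += dZ * dt
        z = rng.standard_normal(3)
        nX = nX * decay + kick * z[0]
        nY = nY * decay + kick * z[1]
        nZ = nZ * decay + kick * z[2]
        if traj is not None:
            proj = project_populations((X, Y, Z))
            traj.append((t + dt, X, Y, Z, *proj))
        proj = project_populations((X, Y, Z))
        mx = max(proj)
        if mx >= p.threshold:
            decision = int(np.argmax(proj)) + 1
            rt = t + dt
            break
        if not math.isfinite(X + Y + Z):
            raise FloatingPointError("decision trajectory diverged before threshold")
    traj_arr = np.array(traj) if traj else None
    return decision, rt, traj_arr


def save_decision_trajectory(trajectory: np.ndarray, path) -> None:
    """Write a decision trajectory as TSV (t, X, Y, Z, p1..p4)."""
    import pandas as pd

    cols = ["t", "X", "Y", "Z", "p1", "p2", "p3", "p4"]
    pd.DataFrame(trajectory, columns=cols).to_csv(path, sep="\t", index=False)
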