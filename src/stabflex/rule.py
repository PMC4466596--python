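"""Reduced two-dimensional dynamics of the rule working-memory module.

The state is the pair of NMDA synaptic gating variables ``(S1, S2)`` of
the two rule-selective populations.  Firing rates follow instantaneously
from the gating variables through an effective transfer function whose
gain, threshold and curvature are corrected for fast AMPA-mediated
recurrence, and the gating variables relax with the slow NMDA time
constant while being charged by the rates:

    dS_i/dt = -S_i/tau_NMDA + (1 - S_i) * gamma * r_i / 1000 + noise_i

with time in ms and rates in Hz.  At standard scaling parameters the
noise-free system has three stable fixed points: a symmetric spontaneous
state at ~3 Hz and two asymmetric high-activity states, one per rule.

Noise model
-----------
Finite-size fluctuations are reintroduced as an Ornstein-Uhlenbeck
process per population with correlation time ``tau_AMPA`` = 2 ms.  The
single noise parameter ``sigma_rule`` is *defined* through the diffusion
coefficient of the equivalent white-noise (Fokker-Planck) description,

    D = (sigma_rule / 2)**2   [1/s],

and the OU amplitude is chosen so that its white-noise-limit diffusion
equals D.  This makes trial simulations, the steady-state landscape and
the minimal-action machinery all refer to the same stochastic process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysioConstants

__all__ = [
    "RuleParams",
    "EffectiveCouplings",
    "RuleState",
    "compute_effective_couplings",
    "rate_transfer",
    "rule_drift",
    "simulate_rule",
    "find_fixed_points",
    "diffusion_coefficient",
    "ou_stationary_std",
]


@dataclass(frozen=True)
class RuleParams:
    """Subject-specific parameters of the rule module.

    ``s_NMDA`` and ``s_GABA`` scale the NMDA and GABA conductances onto
    excitatory cells; ``sigma_rule`` sets the noise level (see module
    docstring).  Negative ``sigma_rule`` values are canonicalized by
    absolute value since only its square enters the dynamics.
    """

    s_NMDA: float = 1.0
    s_GABA: float = 1.0
    sigma_rule: float = 0.1

    def canonical(self) -> "RuleParams":
        return RuleParams(self.s_NMDA, self.s_GABA, abs(self.sigma_rule))


@dataclass(frozen=True)
class EffectiveCouplings:
    """Effective couplings and baseline current of the reduced module."""

    J_N11: float
    J_N12: float
    J_A11: float
    J_A12: float
    I0: float
    l: float
    m: float
    n: float
    psi_ns: float
    g_NMDAeff_E: float
    g_NMDAeff_I: float
    eta: float

    # printed identities of the symmetric circuit
    @property
    def J_N22(self) -> float:
        return self.J_N11

    @property
    def J_N21(self) -> float:
        return self.J_N12

    @property
    def J_A22(self) -> float:
        return self.J_A11

    @property
    def J_A21(self) -> float:
        return self.J_A12


@dataclass
class RuleState:
    """Instantaneous state of the rule module."""

    S1: float
    S2: float
    Snoise1: float = 0.0
    Snoise2: float = 0.0
    t: float = 0.0


def compute_effective_couplings(
    params: RuleParams, consts: PhysioConstants = DEFAULT_CONSTANTS
) -> EffectiveCouplings:
    """Map physiological constants onto the reduced couplings.

    The excitatory populations receive direct recurrent excitation
    (NMDA and AMPA, weighted ``w+`` within a pool and ``w-`` across
    pools) and disynaptic inhibition: selective activity drives the
    interneuron pool, whose linearized rate response (gain
    ``c_I/g_I2``, attenuated by its own GABAergic self-inhibition by
    the factor ``eta``) converts into a GABA conductance on the
    excitatory cells.  The baseline current ``I0`` collects the
    condition-independent drives: external input (``l * r_ext``),
    the nonselective pool through AMPA (``m * r_ns``) and NMDA
    (``n * psi_ns``), and the interneurons' intrinsic offset.
    """
    c = consts
    p = params.canonical()

    g_NMDA_E = p.s_NMDA * c.g_NMDA_E
    g_GABA_E = p.s_GABA * c.g_GABA_E

    # voltage-dependent (magnesium-block) correction of NMDA conductances
    den_E = 1.0 + math.exp(-0.062 * c.V_E) / 3.57
    den_I = 1.0 + math.exp(-0.062 * c.V_I) / 3.57
    if den_E == 0.0 or den_I == 0.0:
        raise ValueError("invalid constants: NMDA voltage correction degenerate")
    gNeff_E = g_NMDA_E / den_E
    gNeff_I = c.g_NMDA_I / den_I

    # interneuron self-inhibition attenuation of the linearized response
    eta = 1.0 / (
        1.0
        + (c.c_I / c.g_I2)
        * c.g_GABA_I
        * (c.V_I - c.V_I_rev)
        * c.C_I
        * (c.tau_GABA / 1000.0)
    )

    # disynaptic-inhibition loop prefactor: GABA conductance on E cells
    # per unit interneuron drive current
    L = (
        g_GABA_E
        * (c.V_E - c.V_I_rev)
        * (c.tau_GABA / 1000.0)
        * c.C_I
        * (c.c_I * eta / c.g_I2)
    )

    fCE = c.f * c.C_E
    tA = c.tau_AMPA / 1000.0

    J_N11 = L * gNeff_I * c.V_I * fCE - gNeff_E * c.V_E * fCE * c.w_plus
    J_N12 = gNeff_E * c.V_E * fCE * c.w_minus - L * gNeff_I * c.V_I * fCE
    J_A11 = L * c.g_AMPA_I * c.V_I * tA * fCE - c.g_AMPA_E * c.V_E * tA * fCE * c.w_plus
    J_A12 = (
        c.g_AMPA_E * c.V_E * tA * fCE * c.w_minus
        - L * c.g_AMPA_I * c.V_I * tA * fCE
    )

    l = L * c.g_AMPAext_I * c.V_I * tA * c.C_ext - c.g_AMPAext_E * c.V_E * tA * c.C_ext
    ns = (1.0 - 2.0 * c.f) * c.C_E
    m = L * c.g_AMPA_I * c.V_I * tA * ns - c.g_AMPA_E * c.V_E * tA * ns * c.w_minus
    n = L * gNeff_I * c.V_I * ns - gNeff_E * c.V_E * ns * c.w_minus

    x = c.gamma * c.tau_NMDA * c.r_ns / 1000.0
    psi_ns = x / (1.0 + x)

    I0 = (
        l * c.r_ext
        + m * c.r_ns
        + n * psi_ns
        + g_GABA_E
        * (c.V_E - c.V_I_rev)
        * (c.tau_GABA / 1000.0)
        * c.C_I
        * (eta * c.I_I / c.g_I2 - psi_ns * c.r0)
    )

    vals = (J_N11, J_N12, J_A11, J_A12, I0, l, m, n)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("invalid constants: non-finite effective coupling")

    return EffectiveCouplings(
        J_N11=J_N11,
        J_N12=J_N12,
        J_A11=J_A11,
        J_A12=J_A12,
        I0=I0,
        l=l,
        m=m,
        n=n,
        psi_ns=psi_ns,
        g_NMDAeff_E=gNeff_E,
        g_NMDAeff_I=gNeff_I,
        eta=eta,
    )


def rate_transfer(x_self, x_other, J_A_self: float, J_A_cross: float):
    """Effective firing-rate transfer function H (Hz).

    The gain ``a``, threshold ``b`` and curvature ``d`` of the base f-I
    curve are corrected for fast recurrent AMPA self-coupling; the
    cross-population AMPA contribution ``f_A`` enters only while the
    other population's effective current exceeds 0.4 (Heaviside with
    theta(0) = 0).  The removable singularity of ``u/(1-exp(-d*u))`` at
    u = 0 takes its limit value 1/d.
    """
    a = 239400.0 * J_A_self + 270.0
    b = 97000.0 * J_A_self + 108.0
    d = -30.0 * J_A_self + 0.1540
    x_other = np.asarray(x_other, dtype=float)
    f_A = J_A_cross * (-276.0 * x_other + 106.0) * (x_other > 0.4)
    u = a * np.asarray(x_self, dtype=float) - f_A - b
    with np.errstate(over="ignore", invalid="ignore"):
        den = -np.expm1(-d * u)
        out = np.where(np.abs(d * u) < 1e-10, 1.0 / d, u / np.where(den == 0, 1.0, den))
    return out if out.ndim else float(out)


def rule_drift(
    state: RuleState,
    couplings: EffectiveCouplings,
    I1: float = 0.0,
    I2: float = 0.0,
):
    """Noise-free drift of the gating variables (1/ms) and current rates (Hz)."""
    c = DEFAULT_CONSTANTS
    x1 = couplings.J_N11 * state.S1 - couplings.J_N12 * state.S2 + couplings.I0 + I1
    x2 = couplings.J_N22 * state.S2 - couplings.J_N21 * state.S1 + couplings.I0 + I2
    r1 = rate_transfer(x1, x2, couplings.J_A11, couplings.J_A12)
    r2 = rate_transfer(x2, x1, couplings.J_A22, couplings.J_A21)
    dS1 = -state.S1 / c.tau_NMDA + (1.0 - state.S1) * c.gamma * r1 / 1000.0
    dS2 = -state.S2 / c.tau_NMDA + (1.0 - state.S2) * c.gamma * r2 / 1000.0
    return dS1, dS2, r1, r2


def _drift_arrays(S1, S2, couplings: EffectiveCouplings, I1=0.0, I2=0.0):
    """Vectorized drift on arrays of gating values (time unit: ms)."""
    c = DEFAULT_CONSTANTS
    x1 = couplings.J_N11 * S1 - couplings.J_N12 * S2 + couplings.I0 + I1
    x2 = couplings.J_N22 * S2 - couplings.J_N21 * S1 + couplings.I0 + I2
    r1 = rate_transfer(x1, x2, couplings.J_A11, couplings.J_A12)
    r2 = rate_transfer(x2, x1, couplings.J_A22, couplings.J_A21)
    dS1 = -S1 / c.tau_NMDA + (1.0 - S1) * c.gamma * r1 / 1000.0
    dS2 = -S2 / c.tau_NMDA + (1.0 - S2) * c.gamma * r2 / 1000.0
    return dS1, dS2, r1, r2


def diffusion_coefficient(sigma_rule: float, per: str = "s") -> float:
    """White-noise diffusion coefficient D = (sigma_rule/2)^2.

    ``per="s"`` returns D in 1/s (the landscape/action convention),
    ``per="ms"`` in 1/ms (the integration convention).
    """
    D = (abs(sigma_rule) / 2.0) ** 2
    if per == "s":
        return D
    if per == "ms":
        return D / 1000.0
    raise ValueError("per must be 's' or 'ms'")


def ou_stationary_std(sigma_rule: float, tau_AMPA: float = 2.0) -> float:
    """Stationary std of the OU noise (1/ms) realizing diffusion D.

    An OU process with correlation time ``tau`` and stationary variance
    ``v`` acts on slow variables like white noise of intensity
    ``v * tau``; matching D (in 1/ms) fixes ``v = D_ms / tau``.
    """
    D_ms = diffusion_coefficient(sigma_rule, per="ms")
    return math.sqrt(D_ms / tau_AMPA)


def simulate_rule(
    initial: RuleState,
    params: RuleParams,
    couplings: EffectiveCouplings,
    input_schedule,
    duration: float,
    dt: float = 0.5,
    rng_seed: int | None = None,
    record_every: int = 1,
):
    """Integrate the stochastic rule module (Euler-Maruyama + exact OU).

    Parameters
    ----------
    input_schedule : callable ``t -> (I1, I2)`` or pair of scalars
        Selective input currents as a function of time (ms).
    duration, dt : float
        Total time and step, ms.  ``dt`` must not exceed tau_AMPA/2 so
        the OU process is resolved.

    Returns
    -------
    dict with arrays ``t, S1, S2, r1, r2, Snoise1, Snoise2``.
    """
    c = DEFAULT_CONSTANTS
    if dt > c.tau_AMPA / 2.0:
        raise ValueError(f"dt={dt} too large: must be <= tau_AMPA/2 = {c.tau_AMPA/2}")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    if callable(input_schedule):
        sched = input_schedule
    else:
        I1c, I2c = input_schedule
        sched = lambda t: (I1c, I2c)  # noqa: E731

    rng = np.random.default_rng(rng_seed)
    p = params.canonical()
    sd_ss = ou_stationary_std(p.sigma_rule, c.tau_AMPA)
    decay = math.exp(-dt / c.tau_AMPA)
    kick = sd_ss * math.sqrt(1.0 - decay * decay)

    S1, S2 = float(initial.S1), float(initial.S2)
    n1, n2 = float(initial.Snoise1), float(initial.Snoise2)
    n_rec = n_steps // record_every + 1
    out = {k: np.empty(n_rec) for k in ("t", "S1", "S2", "r1", "r2", "Snoise1", "Snoise2")}
    j = 0
    for i in range(n_steps + 1):
        t = i * dt
        I1, I2 = sched(t)
        st = RuleState(S1, S2, n1, n2, t)
        dS1, dS2, r1, r2 = rule_drift(st, couplings, I1, I2)
        if i % record_every == 0 and j < n_rec:
            for k, v in (("t", t), ("S1", S1), ("S2", S2), ("r1", r1),
                         ("r2", r2), ("Snoise1", n1), ("Snoise2", n2)):
                out[k][j] = v
            j += 1
        if i == n_steps:
            break
        S1 = min(1.0, max(0.0, S1 + (dS1 + n1) * dt))
        S2 = min(1.0, max(0.0, S2 + (dS2 + n2) * dt))
        z = rng.standard_normal(2)
        n1 = n1 * decay + kick * z[0]
        n2 = n2 * decay + kick * z[1]
    for k in out:
        out[k] = out[k][:j]
    return out


def save_trajectory(trajectory: dict, path) -> None:
    """Write a simulated rule trajectory as TSV (t, S1, S2, r1, r2, noise)."""
    import pandas as pd

    pd.DataFrame(trajectory).to_csv(path, sep="\t", index=False)


def load_trajectory(path) -> dict:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {k: df[k].to_numpy() for k in df.columns}


def find_fixed_points(
    params: RuleParams,
    I1: float = 0.0,
    I2: float = 0.0,
    consts: PhysioConstants = DEFAULT_CONSTANTS,
    n_grid: int = 5,
    tol: float = 1e-10,
):
    """Locate fixed points of the noise-free drift by multi-start rooting.

    Returns a list of ``(S1, S2, r1, r2, stable)`` tuples, duplicates
    merged within 1e-6, sorted by S1.  Stability is read off the sign of
    the numerically evaluated Jacobian's eigenvalue real parts.
    """
    from scipy.optimize import fsolve

    cp = compute_effective_couplings(params, consts)

    def F(S):
        d1, d2, _, _ = _drift_arrays(S[0], S[1], cp, I1, I2)
        return [d1 * 1000.0, d2 * 1000.0]

    found: list[np.ndarray] = []
    grid = np.linspace(0.02, 0.98, n_grid)
    for a in grid:
        for b in grid:
            sol, _, ier, _ = fsolve(F, [a, b], full_output=True, xtol=tol)
            if ier != 1:
                continue
            if not (-0.05 <= sol[0] <= 1.05 and -0.05 <= sol[1] <= 1.05):
                continue
            if any(np.max(np.abs(sol - p)) < 1e-6 for p in found):
                continue
            found.append(sol)
    if not found:
        import warnings

        warnings.warn("no fixed point converged", stacklevel=2)
        return []

    results = []
    eps = 1e-7
    for p in found:
        d1, d2, r1, r2 = _drift_arrays(p[0], p[1], cp, I1, I2)
        J = np.empty((2, 2))
        for k in range(2):
            q = p.copy()
            q[k] += eps
            e1, e2, _, _ = _drift_arrays(q[0], q[1], cp, I1, I2)
            J[0, k] = (e1 - d1) / eps
            J[1, k] = (e2 - d2) / eps
        stable = bool(np.all(np.linalg.eigvals(J).real < 0))
        results.append((float(p[0]), float(p[1]), float(r1), float(r2), stable))
    results.sort(key=lambda r: (r[0], r[1]))
    return results


def settle_to_attractor(
    couplings: EffectiveCouplings,
    start: tuple[float, float] = (0.8, 0.1),
    max_ms: float = 2000.0,
    dt: float = 0.5,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Noise-free integration from ``start`` until the drift vanishes.

    Used to initialize trials at the rule-1 high-activity attractor.
    """
    from ._kernels import settle_kernel

    return settle_kernel(
        start[0],
        start[1],
        couplings.J_N11,
        couplings.J_N12,
        couplings.J_A11,
        couplings.J_A12,
        couplings.I0,
        dt,
        max_ms,
        tol,
    )
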