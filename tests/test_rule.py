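"""Rule-module dynamics: couplings, transfer function, drift, fixed points."""

import math

import numpy as np
import pytest

from stabflex.constants import DEFAULT_CONSTANTS, PhysioConstants
from stabflex.rule import (
    RuleParams,
    RuleState,
    compute_effective_couplings,
    diffusion_coefficient,
    find_fixed_points,
    ou_stationary_std,
    rate_transfer,
    rule_drift,
    simulate_rule,
)


def test_w_minus_balances_potentiation():
    c = DEFAULT_CONSTANTS
    assert c.w_minus == pytest.approx(1.0 - c.f * (c.w_plus - 1.0) / (1.0 - c.f), abs=1e-15)
    assert c.w_minus == pytest.approx(0.88, abs=1e-12)


def test_constants_validation():
    with pytest.raises(ValueError):
        PhysioConstants(C_E=0.9)  # C_E + C_I != 1
    with pytest.raises(ValueError):
        PhysioConstants(g_NMDA_E=-0.3)
    with pytest.raises(ValueError):
        PhysioConstants(V_E=53.4)


def test_coupling_symmetry_identities(standard_couplings):
    cp = standard_couplings
    assert cp.J_N22 == cp.J_N11
    assert cp.J_N21 == cp.J_N12
    assert cp.J_A22 == cp.J_A11
    assert cp.J_A21 == cp.J_A12
    for v in (cp.J_N11, cp.J_N12, cp.J_A11, cp.J_A12, cp.I0):
        assert math.isfinite(v)


def test_couplings_match_highprecision_transcription(standard_couplings):
    """Line-by-line re-evaluation of the coupling formulas with sympy."""
    import sympy as sm

    c = DEFAULT_CONSTANTS
    R = sm.Rational
    V_E, V_I, V_rev = R(-534, 10), R(-511, 10), R(-70)
    f, C_E, C_I, C_ext = R(15, 100), R(8, 10), R(2, 10), R(800)
    tau_G, tau_A, tau_N = R(10), R(2), R(100)
    c_I, I_I, g_I2 = R(615), R(177), R(17876, 10000)
    r_ext, r_ns, r0 = R(3), R(2), R(113721, 10000)
    gAe_E, gA_E, gN_E, gG_E = R(21, 10000), R(1, 10), R(3, 10), R(13, 10)
    gAe_I, gA_I, gN_I, gG_I = R(162, 100000), R(86, 1000), R(258, 1000), R(1)
    w_p = R(168, 100)
    w_m = 1 - f * (w_p - 1) / (1 - f)
    gamma = R(641, 1000)

    gNeff_E = gN_E / (1 + sm.exp(-R(62, 1000) * V_E) / R(357, 100))
    gNeff_I = gN_I / (1 + sm.exp(-R(62, 1000) * V_I) / R(357, 100))
    eta = 1 / (1 + (c_I / g_I2) * gG_I * (V_I - V_rev) * C_I * tau_G / 1000)
    L = gG_E * (V_E - V_rev) * (tau_G / 1000) * C_I * (c_I * eta / g_I2)
    fCE = f * C_E
    tA = tau_A / 1000
    JN11 = L * gNeff_I * V_I * fCE - gNeff_E * V_E * fCE * w_p
    JN12 = gNeff_E * V_E * fCE * w_m - L * gNeff_I * V_I * fCE
    JA11 = L * gA_I * V_I * tA * fCE - gA_E * V_E * tA * fCE * w_p
    JA12 = gA_E * V_E * tA * fCE * w_m - L * gA_I * V_I * tA * fCE
    l = L * gAe_I * V_I * tA * C_ext - gAe_E * V_E * tA * C_ext
    ns = (1 - 2 * f) * C_E
    m = L * gA_I * V_I * tA * ns - gA_E * V_E * tA * ns * w_m
    n = L * gNeff_I * V_I * ns - gNeff_E * V_E * ns * w_m
    x = gamma * tau_N * r_ns / 1000
    psi = x / (1 + x)
    I0 = l * r_ext + m * r_ns + n * psi + gG_E * (V_E - V_rev) * (tau_G / 1000) * C_I * (
        eta * I_I / g_I2 - psi * r0
    )

    cp = standard_couplings
    for got, want in [
        (cp.J_N11, JN11),
        (cp.J_N12, JN12),
        (cp.J_A11, JA11),
        (cp.J_A12, JA12),
        (cp.l, l),
        (cp.m, m),
        (cp.n, n),
        (cp.psi_ns, psi),
        (cp.I0, I0),
        (cp.eta, eta),
    ]:
        assert got == pytest.approx(float(sm.N(want, 30)), rel=1e-12)


def test_scaling_parameters_enter_linearly():
    cp1 = compute_effective_couplings(RuleParams(s_NMDA=1.1, s_GABA=1.0))
    cp0 = compute_effective_couplings(RuleParams())
    # s_NMDA scales only the NMDA conductance onto excitatory cells
    assert cp1.g_NMDAeff_E == pytest.approx(1.1 * cp0.g_NMDAeff_E, rel=1e-12)
    assert cp1.g_NMDAeff_I == cp0.g_NMDAeff_I


class TestRateTransfer:
    def test_removable_singularity_limit(self, standard_couplings):
        cp = standard_couplings
        a = 239400.0 * cp.J_A11 + 270.0
        b = 97000.0 * cp.J_A11 + 108.0
        d = -30.0 * cp.J_A11 + 0.1540
        x0 = b / a  # numerator vanishes (x_other below threshold)
        h0 = rate_transfer(x0, 0.0, cp.J_A11, cp.J_A12)
        assert h0 == pytest.approx(1.0 / d, rel=1e-9)
        # continuity across the singularity
        eps = 1e-7
        assert rate_transfer(x0 + eps, 0.0, cp.J_A11, cp.J_A12) == pytest.approx(h0, rel=1e-4)

    def test_asymptotic_linearity(self, standard_couplings):
        cp = standard_couplings
        a = 239400.0 * cp.J_A11 + 270.0
        b = 97000.0 * cp.J_A11 + 108.0
        x = 5.0
        assert rate_transfer(x, 0.0, cp.J_A11, cp.J_A12) == pytest.approx(a * x - b, rel=1e-10)

    def test_heaviside_zero_convention(self, standard_couplings):
        cp = standard_couplings
        # at x_other exactly 0.4 the cross-AMPA term contributes nothing
        h_at = rate_transfer(0.4, 0.4, cp.J_A11, cp.J_A12)
        h_off = rate_transfer(0.4, 0.0, cp.J_A11, 0.0)
        assert h_at == pytest.approx(h_off, rel=1e-12)
        # just above threshold it does contribute
        h_above = rate_transfer(0.4, 0.4 + 1e-6, cp.J_A11, cp.J_A12)
        assert h_above != pytest.approx(h_at, rel=1e-12)

    def test_nonnegative(self, standard_couplings):
        cp = standard_couplings
        xs = np.linspace(-0.5, 1.5, 101)
        h = rate_transfer(xs, 0.3, cp.J_A11, cp.J_A12)
        assert np.all(h >= 0)


class TestRuleDrift:
    def test_zero_at_fixed_points(self, standard_couplings):
        for s1, s2, r1, r2, stable in find_fixed_points(RuleParams()):
            d1, d2, _, _ = rule_drift(RuleState(s1, s2), standard_couplings)
            assert abs(d1) < 1e-10 and abs(d2) < 1e-10

    def test_population_exchange_symmetry(self, standard_couplings):
        for s in (0.1, 0.33, 0.7):
            d1, d2, r1, r2 = rule_drift(RuleState(s, s), standard_couplings, 0.02, 0.02)
            assert d1 == pytest.approx(d2, abs=1e-15)
            assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_independent_transcription(self, standard_couplings, rng):
        cp = standard_couplings
        tau_N, gamma = 100.0, 0.641

        def H(x_s, x_o, Jii, Jij):
            a = 239400 * Jii + 270
            b = 97000 * Jii + 108
            d = -30 * Jii + 0.154
            fA = Jij * (-276 * x_o + 106) if x_o > 0.4 else 0.0
            u = a * x_s - fA - b
            return 1 / d if abs(u) < 1e-12 else u / (1 - math.exp(-d * u))

        for _ in range(20):
            s1, s2 = rng.uniform(0, 1, 2)
            i1, i2 = rng.uniform(-0.05, 0.05, 2)
            x1 = cp.J_N11 * s1 - cp.J_N12 * s2 + cp.I0 + i1
            x2 = cp.J_N11 * s2 - cp.J_N12 * s1 + cp.I0 + i2
            r1 = H(x1, x2, cp.J_A11, cp.J_A12)
            r2 = H(x2, x1, cp.J_A11, cp.J_A12)
            want1 = -s1 / tau_N + (1 - s1) * gamma * r1 / 1000
            want2 = -s2 / tau_N + (1 - s2) * gamma * r2 / 1000
            d1, d2, _, _ = rule_drift(RuleState(s1, s2), cp, i1, i2)
            assert d1 == pytest.approx(want1, rel=1e-10, abs=1e-14)
            assert d2 == pytest.approx(want2, rel=1e-10, abs=1e-14)


class TestFixedPoints:
    def test_three_stable_states(self):
        fps = find_fixed_points(RuleParams())
        stable = [f for f in fps if f[4]]
        assert len(stable) == 3

    def test_high_states_mirror_each_other(self):
        stable = [f for f in find_fixed_points(RuleParams()) if f[4]]
        asym = sorted([f for f in stable if abs(f[0] - f[1]) > 1e-3])
        assert len(asym) == 2
        assert asym[0][0] == pytest.approx(asym[1][1], abs=1e-6)
        assert asym[0][1] == pytest.approx(asym[1][0], abs=1e-6)
        sym = [f for f in stable if abs(f[0] - f[1]) <= 1e-3]
        assert len(sym) == 1
        assert sym[0][2] == pytest.approx(sym[0][3], abs=1e-8)

    def test_small_scaling_shifts_preserve_structure(self):
        # a slightly stronger NMDA keeps the memory states
        stable = [f for f in find_fixed_points(RuleParams(s_NMDA=1.005)) if f[4]]
        assert sum(abs(f[0] - f[1]) > 1e-3 for f in stable) == 2
        # a slightly stronger GABA keeps the spontaneous state
        stable = [f for f in find_fixed_points(RuleParams(s_GABA=1.005)) if f[4]]
        assert sum(abs(f[0] - f[1]) <= 1e-3 for f in stable) == 1


class TestSimulateRule:
    def test_rejects_large_dt(self, standard_couplings):
        with pytest.raises(ValueError, match="dt"):
            simulate_rule(
                RuleState(0.5, 0.5), RuleParams(), standard_couplings, (0, 0), 10.0, dt=2.0
            )

    def test_noise_free_settles_to_rule1(self, standard_couplings):
        out = simulate_rule(
            RuleState(0.8, 0.1),
            RuleParams(sigma_rule=0.0),
            standard_couplings,
            (0.0, 0.0),
            2000.0,
            dt=0.5,
            rng_seed=0,
        )
        stable = [f for f in find_fixed_points(RuleParams()) if f[4]]
        rule1 = max(stable, key=lambda f: f[0] - f[1])
        assert out["S1"][-1] == pytest.approx(rule1[0], abs=1e-4)
        assert out["S2"][-1] == pytest.approx(rule1[1], abs=1e-4)

    def test_noise_free_fixed_point_is_stationary(self, standard_couplings):
        sym = [f for f in find_fixed_points(RuleParams()) if f[4] and abs(f[0] - f[1]) < 1e-3][0]
        out = simulate_rule(
            RuleState(sym[0], sym[1]),
            RuleParams(sigma_rule=0.0),
            standard_couplings,
            (0.0, 0.0),
            500.0,
            dt=0.5,
        )
        assert np.max(np.abs(out["S1"] - sym[0])) < 1e-6
        assert np.max(np.abs(out["S2"] - sym[1])) < 1e-6

    def test_reproducible_under_seed(self, standard_couplings):
        kw = dict(
            initial=RuleState(0.3, 0.3),
            params=RuleParams(sigma_rule=0.2),
            couplings=standard_couplings,
            input_schedule=(0.0, 0.0),
            duration=200.0,
            dt=0.5,
            rng_seed=42,
        )
        a = simulate_rule(**kw)
        b = simulate_rule(**kw)
        assert np.array_equal(a["S1"], b["S1"])
        assert np.array_equal(a["Snoise2"], b["Snoise2"])

    def test_ou_noise_realizes_diffusion_coefficient(self, standard_couplings):
        """The OU stationary variance matches D/tau_AMPA within 5%."""
        sigma = 0.2
        out = simulate_rule(
            RuleState(0.15, 0.15),
            RuleParams(sigma_rule=sigma),
            standard_couplings,
            (0.0, 0.0),
            2e5,
            dt=0.5,
            rng_seed=3,
        )
        want = ou_stationary_std(sigma) ** 2
        got = np.var(np.concatenate([out["Snoise1"][400:], out["Snoise2"][400:]]))
        assert got == pytest.approx(want, rel=0.05)
        assert want == pytest.approx(
            diffusion_coefficient(sigma, per="ms") / DEFAULT_CONSTANTS.tau_AMPA, rel=1e-12
        )

    def test_monotone_convergence_inside_basins(self, standard_couplings):
        stable = [f for f in find_fixed_points(RuleParams()) if f[4]]
        for s1, s2, *_ in stable:
            start = (min(0.99, s1 + 0.02), max(0.01, s2 - 0.02))
            out = simulate_rule(
                RuleState(*start),
                RuleParams(sigma_rule=0.0),
                standard_couplings,
                (0.0, 0.0),
                1000.0,
                dt=0.5,
            )
            dist = np.hypot(out["S1"] - s1, out["S2"] - s2)
            assert np.all(np.diff(dist) <= 1e-9)
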