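"""Task design, condition-dependent inputs, trial simulation and log I/O.

The paradigm probes cognitive stability and flexibility with digit
judgments: 300 two-second trials (stimuli shown for 900 ms) of which
240 are baseline (single digit above fixation, parity judgment), and
20 each are distractor (second, darker digit below fixation: keep the
parity rule), switch (lower digit brighter: apply the magnitude rule
to it) and ambiguous (near-equal brightness; excluded from modeling).
Critical trials are separated by 3-6 baseline trials.

A simulated trial initializes the rule module at the rule-1 (parity)
attractor, applies brightness-cue inputs to the rule module and
stimulus/rule-feed inputs to the decision module for 900 ms, then lets
both run input-free until 2000 ms; the first decision-pool projection
to cross threshold gives choice and reaction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._kernels import simulate_trials_kernel
from .params import FittedParams
from .rule import (
    RuleParams,
    compute_effective_couplings,
    diffusion_coefficient,
    settle_to_attractor,
)

__all__ = [
    "CONDITIONS",
    "DECISIONS",
    "SessionDesign",
    "TrialSpec",
    "TrialOutcome",
    "BehavioralDataset",
    "NotModeledError",
    "generate_session",
    "condition_inputs",
    "decision_pool_labels",
    "simulate_trial",
    "simulate_condition",
    "simulate_dataset",
    "simulate_session",
    "read_behavior_log",
    "write_behavior_log",
]

CONDITIONS = ("baseline", "distractor", "switch", "ambiguous")
MODELED_CONDITIONS = ("baseline", "distractor", "switch")
DECISIONS = ("odd", "even", "gt5", "lt5")
DIGITS = (1, 2, 3, 4, 6, 7, 8, 9)

BASELINE_GRAY = 127
BRIGHT_RANGE = (169, 195)
AMBIGUOUS_RANGE = (117, 137)


class NotModeledError(ValueError):
    """Raised when a computation is requested for the ambiguous condition."""


@dataclass(frozen=True)
class SessionDesign:
    n_baseline: int = 240
    n_distractor: int = 20
    n_switch: int = 20
    n_ambiguous: int = 20
    trial_duration_ms: float = 2000.0
    stimulus_duration_ms: float = 900.0
    min_gap: int = 3
    max_gap: int = 6

    @property
    def n_trials(self) -> int:
        return self.n_baseline + self.n_distractor + self.n_switch + self.n_ambiguous

    @property
    def n_critical(self) -> int:
        return self.n_distractor + self.n_switch + self.n_ambiguous


@dataclass(frozen=True)
class TrialSpec:
    index: int
    condition: str
    upper_digit: int
    lower_digit: int | None = None
    gray_upper: int = BASELINE_GRAY
    gray_lower: int | None = None

    @property
    def correct_decision(self) -> str | None:
        """Rule-consistent decision; None for the ambiguous condition."""
        if self.condition in ("baseline", "distractor"):
            return "odd" if self.upper_digit % 2 == 1 else "even"
        if self.condition == "switch":
            return "gt5" if self.lower_digit > 5 else "lt5"
        return None


@dataclass(frozen=True)
class TrialOutcome:
    spec: TrialSpec
    decision: str  # one of DECISIONS or "none"
    rt_ms: float  # nan when decision == "none"
    correct: bool


def generate_session(design: SessionDesign = SessionDesign(), rng_seed: int | None = None):
    """Generate one pseudorandomized session as a list of TrialSpec.

    Critical (distractor/switch/ambiguous) trials are preceded by 3-6
    baseline trials each; the gap lengths are a uniformly sampled
    composition of the baseline count, so every consecutive pair of
    critical trials is separated by 3-6 baseline trials exactly.
    """
    d = design
    rng = np.random.default_rng(rng_seed)
    k = d.n_critical
    lo, hi = d.min_gap, d.max_gap
    if not (k * lo <= d.n_baseline <= k * hi):
        raise ValueError(
            f"unsatisfiable design: {d.n_baseline} baseline trials cannot be split "
            f"into {k} gaps of {lo}-{hi}"
        )
    extra = d.n_baseline - k * lo
    cap = hi - lo
    # distribute `extra` increments over k gaps with per-gap capacity `cap`
    slots = rng.choice(k * cap, size=extra, replace=False)
    gaps = np.full(k, lo, dtype=int)
    for s in slots:
        gaps[s // cap] += 1

    crit = (
        ["distractor"] * d.n_distractor
        + ["switch"] * d.n_switch
        + ["ambiguous"] * d.n_ambiguous
    )
    rng.shuffle(crit)

    specs: list[TrialSpec] = []

    def add_baseline(n):
        for _ in range(n):
            specs.append(
                TrialSpec(
                    index=len(specs),
                    condition="baseline",
                    upper_digit=int(rng.choice(DIGITS)),
                )
            )

    for g, cond in zip(gaps, crit):
        add_baseline(int(g))
        upper = int(rng.choice(DIGITS))
        lower = int(rng.choice(DIGITS))
        if cond == "distractor":
            gu = int(rng.integers(BRIGHT_RANGE[0], BRIGHT_RANGE[1] + 1))
            gl = 255 - gu
        elif cond == "switch":
            gl = int(rng.integers(BRIGHT_RANGE[0], BRIGHT_RANGE[1] + 1))
            gu = 255 - gl
        else:  # ambiguous
            gu = BASELINE_GRAY
            gl = int(rng.integers(AMBIGUOUS_RANGE[0], AMBIGUOUS_RANGE[1] + 1))
        specs.append(
            TrialSpec(
                index=len(specs),
                condition=cond,
                upper_digit=upper,
                lower_digit=lower,
                gray_upper=gu,
                gray_lower=gl,
            )
        )
    assert len(specs) == d.n_trials
    return specs


def condition_inputs(spec_or_condition, params: FittedParams) -> tuple[float, float]:
    """Rule-module inputs (I1, I2) for a trial's condition.

    baseline:   I1 = I1_base,                              I2 = 0
    distractor: I1 = I1_base + Ibar_dist + dI_dist/2,      I2 = I1_base + Ibar_dist - dI_dist/2
    switch:     I1 = I1_base + Ibar_switch - dI_switch/2,  I2 = I1_base + Ibar_switch + dI_switch/2
    """
    cond = (
        spec_or_condition.condition
        if isinstance(spec_or_condition, TrialSpec)
        else spec_or_condition
    )
    p = params
    if cond == "baseline":
        return p.I1_base, 0.0
    if cond == "distractor":
        base = p.I1_base + p.Ibar_dist
        return base + 0.5 * p.dI_dist, base - 0.5 * p.dI_dist
    if cond == "switch":
        base = p.I1_base + p.Ibar_switch
        return base - 0.5 * p.dI_switch, base + 0.5 * p.dI_switch
    if cond == "ambiguous":
        raise NotModeledError("the ambiguous condition is not modeled")
    raise ValueError(f"unknown condition {cond!r}")


def _decision_drives(condition: str, params: FittedParams):
    """Stimulus drives (D1..D4) onto the four decision pools.

    Pool 1 receives the correct-parity drive D11, pool 3 the correct-
    magnitude drive D12 (only when a lower digit is shown, i.e. not in
    baseline); the wrong-feature drives are fixed at 0.
    """
    if condition == "baseline":
        return params.D11, 0.0, 0.0, 0.0
    if condition in ("distractor", "switch"):
        return params.D11, 0.0, params.D12, 0.0
    raise NotModeledError(f"condition {condition!r} has no modeled drives")


def decision_pool_labels(spec: TrialSpec) -> tuple[str, str, str, str]:
    """Map the four decision pools onto response labels for one trial.

    Pool 1 is the parity of the upper digit, pool 2 the opposite
    parity; pool 3 is the magnitude class of the lower digit (of the
    upper digit in baseline, where no lower digit exists and the
    magnitude pools are reached only by noise), pool 4 the opposite.
    """
    par = "odd" if spec.upper_digit % 2 == 1 else "even"
    anti_par = "even" if par == "odd" else "odd"
    ref = spec.lower_digit if spec.lower_digit is not None else spec.upper_digit
    mag = "gt5" if ref > 5 else "lt5"
    anti_mag = "lt5" if mag == "gt5" else "gt5"
    return par, anti_par, mag, anti_mag


def _rule1_start(params: FittedParams):
    cp = compute_effective_couplings(RuleParams(params.s_NMDA, params.s_GABA, params.sigma_rule))
    S0 = settle_to_attractor(cp)
    return cp, S0


def simulate_condition(
    condition: str,
    params: FittedParams,
    n_trials: int,
    rng_seed: int,
    dt: float = 0.5,
    noise_stride: int | None = None,
    full_trial: bool = False,
    design: SessionDesign = SessionDesign(),
    _prepared=None,
):
    """Simulate ``n_trials`` of one condition; return (pools, rts, energies).

    ``pools`` are raw decision-pool indices 1-4 (0 = no response);
    mapping onto response labels requires trial digits and is done by
    the callers.  ``noise_stride`` sets how many integration steps one
    Gaussian noise increment spans (default: one increment per 2 ms,
    the OU correlation time of the reference noise model).
    """
    p = params.canonical()
    cp, S0 = _prepared if _prepared is not None else _rule1_start(p)
    I1, I2 = condition_inputs(condition, p)
    D1, D2, D3, D4 = _decision_drives(condition, p)
    if noise_stride is None:
        noise_stride = max(1, int(round(2.0 / dt)))
    n_steps = int(round(design.trial_duration_ms / dt))
    n_kicks = n_steps // noise_stride + 1
    noise = np.random.default_rng(int(rng_seed) % (2**31)).standard_normal(
        (n_trials, n_kicks, 5), dtype=np.float32
    )
    # white-noise-limit diffusion of the gating variables (1/ms)
    D_rule_ms = diffusion_coefficient(p.sigma_rule, per="ms")
    # decision OU (stationary var sigma^2/2, correlation 2 ms) acts on the
    # amplitudes through the 1/tau prefactor: D = (sigma^2/2) * tau_AMPA / tau^2
    D_dec_ms = (p.sigma_decision**2 / 2.0) * 2.0 / (100.0**2)
    pools, rts, energies = simulate_trials_kernel(
        n_trials,
        S0[0],
        S0[1],
        cp.J_N11,
        cp.J_N12,
        cp.J_A11,
        cp.J_A12,
        cp.I0,
        I1,
        I2,
        D1,
        D2,
        D3,
        D4,
        p.c_plus,
        p.beta,
        1.0,
        D_rule_ms,
        D_dec_ms,
        10.0,
        dt,
        noise_stride,
        design.stimulus_duration_ms,
        design.trial_duration_ms,
        full_trial,
        noise,
    )
    return pools, rts, energies


def _outcome_from_pool(spec: TrialSpec, pool: int, rt: float) -> TrialOutcome:
    if pool == 0:
        return TrialOutcome(spec, "none", math.nan, False)
    label = decision_pool_labels(spec)[pool - 1]
    correct = label == spec.correct_decision
    return TrialOutcome(spec, label, float(rt), bool(correct))


def simulate_trial(
    spec: TrialSpec, params: FittedParams, rng_seed: int, dt: float = 0.5
) -> TrialOutcome:
    """Simulate a single trial from its spec."""
    if spec.condition == "ambiguous":
        raise NotModeledError("the ambiguous condition is not simulated")
    pools, rts, _ = simulate_condition(spec.condition, params, 1, rng_seed, dt=dt)
    return _outcome_from_pool(spec, int(pools[0]), float(rts[0]))


class BehavioralDataset:
    """A collection of trial outcomes with tabular access.

    Wraps a DataFrame with columns trial, condition, upper_digit,
    lower_digit, gray_upper, gray_lower, decision, rt_ms, correct.
    """

    COLUMNS = (
        "trial",
        "condition",
        "upper_digit",
        "lower_digit",
        "gray_upper",
        "gray_lower",
        "decision",
        "rt_ms",
        "correct",
    )

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_outcomes(cls, outcomes) -> "BehavioralDataset":
        rows = []
        for o in outcomes:
            s = o.spec
            rows.append(
                dict(
                    trial=s.index,
                    condition=s.condition,
                    upper_digit=s.upper_digit,
                    lower_digit=s.lower_digit,
                    gray_upper=s.gray_upper,
                    gray_lower=s.gray_lower,
                    decision=o.decision,
                    rt_ms=o.rt_ms,
                    correct=o.correct,
                )
            )
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def condition_counts(self) -> pd.Series:
        return self.df["condition"].value_counts()

    def validate(self) -> None:
        df = self.df
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValueError(f"unknown condition in rows {df.index[bad].tolist()}")
        bad = ~df["decision"].isin(DECISIONS + ("none",))
        if bad.any():
            raise ValueError(f"unknown decision in rows {df.index[bad].tolist()}")
        responded = df["decision"] != "none"
        rt = df.loc[responded, "rt_ms"].astype(float)
        if ((rt <= 0) | (rt > 2000)).any():
            raise ValueError("reaction times must lie in (0, 2000] ms")


def simulate_dataset(
    params: FittedParams,
    n_per_condition: int | dict = 1024,
    rng_seed: int | None = None,
    dt: float = 0.5,
    noise_stride: int | None = None,
    full_trial: bool = False,
) -> BehavioralDataset:
    """Simulate independent trials of each modeled condition.

    Digits and gray values are drawn per trial as in a session, but
    trials are grouped by condition (no session ordering); used for the
    likelihood and goodness-of-fit machinery.
    """
    if isinstance(n_per_condition, int):
        counts = {c: n_per_condition for c in MODELED_CONDITIONS}
    else:
        counts = dict(n_per_condition)
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.spawn(len(counts) + 1)
    rng = np.random.default_rng(seeds[-1])
    prepared = _rule1_start(params.canonical())

    outcomes = []
    idx = 0
    for (cond, n), seed in zip(counts.items(), seeds):
        pools, rts, _ = simulate_condition(
            cond,
            params,
            n,
            seed.generate_state(1)[0],
            dt=dt,
            noise_stride=noise_stride,
            full_trial=full_trial,
            _prepared=prepared,
        )
        for j in range(n):
            upper = int(rng.choice(DIGITS))
            lower = int(rng.choice(DIGITS)) if cond != "baseline" else None
            spec = TrialSpec(index=idx, condition=cond, upper_digit=upper, lower_digit=lower)
            outcomes.append(_outcome_from_pool(spec, int(pools[j]), float(rts[j])))
            idx += 1
    return BehavioralDataset.from_outcomes(outcomes)


def simulate_session(
    params: FittedParams,
    design: SessionDesign = SessionDesign(),
    rng_seed: int | None = None,
    dt: float = 0.5,
    noise_stride: int | None = None,
    full_trial: bool = False,
) -> BehavioralDataset:
    """Simulate a full pseudorandomized session (a synthetic subject log).

    Ambiguous trials appear in the log with decision "none" and no
    reaction time; they are never simulated.
    """
    ss = np.random.SeedSequence(rng_seed)
    s_design, *s_conds = ss.spawn(1 + len(MODELED_CONDITIONS))
    specs = generate_session(design, np.random.default_rng(s_design))
    by_cond = {c: [s for s in specs if s.condition == c] for c in MODELED_CONDITIONS}
    prepared = _rule1_start(params.canonical())
    outcomes: dict[int, TrialOutcome] = {}
    for cond, seed in zip(MODELED_CONDITIONS, s_conds):
        group = by_cond[cond]
        if not group:
            continue
        pools, rts, _ = simulate_condition(
            cond,
            params,
            len(group),
            seed.generate_state(1)[0],
            dt=dt,
            noise_stride=noise_stride,
            full_trial=full_trial,
            design=design,
            _prepared=prepared,
        )
        for spec, pool, rt in zip(group, pools, rts):
            outcomes[spec.index] = _outcome_from_pool(spec, int(pool), float(rt))
    ordered = []
    for spec in specs:
        if spec.condition == "ambiguous":
            ordered.append(TrialOutcome(spec, "none", math.nan, False))
        else:
            ordered.append(outcomes[spec.index])
    return BehavioralDataset.from_outcomes(ordered)


def write_behavior_log(dataset: BehavioralDataset, path) -> None:
    """Write a dataset as a UTF-8 tab-separated log with header row."""
    df = dataset.df.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_behavior_log(path) -> BehavioralDataset:
    """Read a behavioral log, validating schema and invariants."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse behavior log {path}: {exc}") from exc
    missing = set(BehavioralDataset.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavior log {path} missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        if row["condition"] not in CONDITIONS:
            raise ValueError(f"line {i + 2}: unknown condition {row['condition']!r}")
        if row["decision"] not in DECISIONS + ("none",):
            raise ValueError(f"line {i + 2}: unknown decision {row['decision']!r}")
        if row["decision"] != "none":
            rt = float(row["rt_ms"])
            if not (0 < rt <= 2000):
                raise ValueError(f"line {i + 2}: rt_ms {rt} outside (0, 2000]")
    ds = BehavioralDataset(df)
    return ds
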