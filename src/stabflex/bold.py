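"""Predicted BOLD regressor from simulated rule-module activity.

The metabolic load of the rule module in a trial is summarized by the
integral of the summed selective-population firing rates over the
trial.  Averaging this energy proxy per (condition, decision) cell and
normalizing to a correct baseline trial yields an energy table; placing
each logged trial's table value at its onset, z-scoring the resulting
time course, and convolving with a canonical double-gamma hemodynamic
response function produces a subject-specific regressor for a GLM of
the fMRI timeseries.  Ambiguous trials contribute no energy impulse
(they are handled as separate nuisance regressors downstream, outside
this package's scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import FittedParams
from .task import (
    DECISIONS,
    MODELED_CONDITIONS,
    BehavioralDataset,
    _rule1_start,
    simulate_condition,
)

__all__ = [
    "EnergyTable",
    "BoldRegressor",
    "trial_energy_table",
    "assemble_timecourse",
    "hrf",
    "convolve_regressor",
    "write_regressor",
    "read_regressor",
]

DECISION_CATEGORIES = DECISIONS + ("none",)


@dataclass
class EnergyTable:
    """Mean spike-rate integral per (condition, decision) cell.

    Values are normalized to the mean over correct baseline trials, so
    the correct-baseline reference is 1 by construction.  Cells never
    visited in simulation fall back to their condition's mean.
    """

    values: dict  # (condition, decision) -> float
    reference: float  # raw Hz*ms of a correct baseline trial

    def __getitem__(self, key):
        return self.values[key]


@dataclass
class BoldRegressor:
    times: np.ndarray  # regressor sample times, s (TR grid)
    values: np.ndarray
    fine_times: np.ndarray  # pre-convolution grid, s
    fine_series: np.ndarray  # z-scored energy impulse series
    sample_dt: float
    tr: float
    hrf_params: dict = field(default_factory=dict)


def trial_energy_table(
    params: FittedParams,
    n_per_cell: int = 1024,
    rng_seed: int = 0,
    dt: float = 0.5,
) -> EnergyTable:
    """Simulate trials per condition and tabulate normalized energies.

    ``n_per_cell`` trials are simulated per *condition* (matching the
    study's 1024) and sorted into (condition, decision) cells by the
    decision taken; the per-trial energy is the full-trial integral
    of r1 + r2 regardless of when the decision fell.
    """
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.spawn(len(MODELED_CONDITIONS) + 1)
    rng = np.random.default_rng(seeds[-1])
    prepared = _rule1_start(params.canonical())

    raw: dict = {}
    correct_baseline: list = []
    all_baseline: list = []
    for cond, seed in zip(MODELED_CONDITIONS, seeds):
        pools, rts, energies = simulate_condition(
            cond,
            params,
            n_per_cell,
            seed.generate_state(1)[0],
            dt=dt,
            full_trial=True,
            _prepared=prepared,
        )
        # random digits assign pool -> label, as in dataset simulation
        par = rng.integers(0, 2, size=n_per_cell)
        mag = rng.integers(0, 2, size=n_per_cell)
        for j in range(n_per_cell):
            pool = int(pools[j])
            if pool == 0:
                label = "none"
            elif pool == 1:
                label = DECISIONS[par[j]]
            elif pool == 2:
                label = DECISIONS[1 - par[j]]
            elif pool == 3:
                label = DECISIONS[2 + mag[j]]
            else:
                label = DECISIONS[2 + (1 - mag[j])]
            raw.setdefault((cond, label), []).append(energies[j])
            if cond == "baseline":
                if pool == 1:
                    correct_baseline.append(energies[j])
                all_baseline.append(energies[j])
    if correct_baseline:
        ref = float(np.mean(correct_baseline))
    else:
        # degenerate parameter sets may produce no correct responses;
        # the baseline-trial mean then anchors the normalization
        import warnings

        warnings.warn(
            "no correct baseline trials simulated; normalizing to the "
            "mean baseline-trial energy",
            stacklevel=2,
        )
        ref = float(np.mean(all_baseline))

    values = {}
    for cond in MODELED_CONDITIONS:
        cells = {d: raw.get((cond, d)) for d in DECISION_CATEGORIES}
        filled = [v for vs in cells.values() if vs for v in vs]
        cond_mean = float(np.mean(filled)) / ref if filled else 1.0
        for d in DECISION_CATEGORIES:
            vs = cells[d]
            values[(cond, d)] = float(np.mean(vs)) / ref if vs else cond_mean
    return EnergyTable(values=values, reference=ref)


def assemble_timecourse(
    log: BehavioralDataset,
    table: EnergyTable,
    sample_dt: float = 0.1,
    trial_duration_s: float = 2.0,
):
    """Place per-trial energies at trial onsets and z-score the series.

    Trial onsets are trial index times the trial duration; ambiguous
    trials contribute nothing.  Returns (times_s, series); a constant
    series (no variance) z-scores to all zeros.
    """
    df = log.df
    n_trials = len(df)
    duration = n_trials * trial_duration_s
    n_samples = int(round(duration / sample_dt))
    times = np.arange(n_samples) * sample_dt
    series = np.zeros(n_samples)
    values = []
    for _, row in df.iterrows():
        if row["condition"] == "ambiguous":
            continue
        v = table.values[(row["condition"], row["decision"])]
        values.append(v)
        onset = float(row["trial"]) * trial_duration_s
        k = int(round(onset / sample_dt))
        if k < n_samples:
            series[k] += v
    # a session with no energy contrast between trials carries no signal
    if not values or np.std(values) < 1e-12:
        return times, np.zeros(n_samples)
    return times, (series - series.mean()) / series.std()


def hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
):
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities (peak at ~5 s, undershoot after
    ~12 s, length conventionally truncated at 32 s); amplitude scaling
    is left to the caller (convolve_regressor normalizes to unit sum).
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    return peak - under / ratio


def convolve_regressor(
    times: np.ndarray,
    series: np.ndarray,
    sample_dt: float = 0.1,
    tr: float = 2.0,
    hrf_length_s: float = 32.0,
    **hrf_kwargs,
) -> BoldRegressor:
    """Convolve a z-scored energy series with the canonical HRF.

    The HRF is sampled on the fine grid, normalized to unit sum, and
    linearly convolved with the series; the result is then read out on
    the TR grid (the scanner's sampling times).
    """
    hrf_defaults = dict(
        peak_delay=6.0, undershoot_delay=16.0, peak_disp=1.0,
        undershoot_disp=1.0, ratio=6.0,
    )
    hrf_defaults.update(hrf_kwargs)
    t_hrf = np.arange(0.0, hrf_length_s, sample_dt)
    kernel = hrf(t_hrf, **hrf_defaults)
    s = kernel.sum()
    if abs(s) > 1e-12:
        kernel = kernel / s
    conv = np.convolve(series, kernel)[: len(series)]
    stride = int(round(tr / sample_dt))
    idx = np.arange(0, len(series), stride)
    return BoldRegressor(
        times=times[idx],
        values=conv[idx],
        fine_times=times,
        fine_series=series,
        sample_dt=sample_dt,
        tr=tr,
        hrf_params=dict(hrf_length_s=hrf_length_s, **hrf_defaults),
    )


def write_regressor(regressor: BoldRegressor, path, seed: int | None = None) -> None:
    """Two-column (time_s, value) TSV with HRF parameters in the header."""
    with open(path, "w", encoding="utf-8") as f:
        f.write(f"# tr={regressor.tr} sample_dt={regressor.sample_dt}")
        for k, v in regressor.hrf_params.items():
            f.write(f" {k}={v}")
        if seed is not None:
            f.write(f" seed={seed}")
        f.write("\n")
        f.write("time_s\tvalue\n")
        for t, v in zip(regressor.times, regressor.values):
            f.write(f"{t:.3f}\t{v:.10g}\n")


def read_regressor(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
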