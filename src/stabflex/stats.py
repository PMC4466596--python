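"""Likelihood machinery: exact multinomial test, two-sample KS probability,
Gaussian shrinkage priors and the composite posterior density.

The likelihood of a subject's behavior given model parameters is the
product, over task conditions, of the multinomial probability of the
observed decision counts under the simulated decision rates, times,
over (condition, decision) cells, the two-sample Kolmogorov-Smirnov
probability that observed and simulated reaction-time samples share a
distribution.  Non-responses are excluded; the multinomial runs over
the four response categories of responded trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .params import FittedParams, Priors
from .task import DECISIONS, MODELED_CONDITIONS, BehavioralDataset

__all__ = [
    "SummaryStats",
    "summarize",
    "exact_multinomial_p",
    "ks2_statistic",
    "ks2_probability",
    "log_likelihood",
    "simulate_summary",
    "log_posterior",
]

MIN_KS_CELL = 3  # RT samples required on both sides for a KS factor


@dataclass
class SummaryStats:
    """Condition-wise decision counts and reaction-time samples.

    ``counts[cond]`` is the 4-vector of responded-decision counts in
    the order ``DECISIONS``; ``n_none[cond]`` the non-response count;
    ``n_total[cond]`` all trials of the condition; ``rts[(cond, dec)]``
    the sorted RT sample of that cell.
    """

    counts: dict = field(default_factory=dict)
    n_none: dict = field(default_factory=dict)
    n_total: dict = field(default_factory=dict)
    rts: dict = field(default_factory=dict)

    def conditions(self):
        return tuple(self.counts.keys())


def summarize(dataset: BehavioralDataset) -> SummaryStats:
    """Compute condition-wise summary statistics of a behavioral dataset."""
    st = SummaryStats()
    df = dataset.df
    for cond in MODELED_CONDITIONS:
        sub = df[df["condition"] == cond]
        if len(sub) == 0:
            continue
        counts = np.array(
            [int((sub["decision"] == d).sum()) for d in DECISIONS], dtype=int
        )
        st.counts[cond] = counts
        st.n_none[cond] = int((sub["decision"] == "none").sum())
        st.n_total[cond] = len(sub)
        for d in DECISIONS:
            rt = sub.loc[sub["decision"] == d, "rt_ms"].astype(float).to_numpy()
            rt = np.sort(rt[np.isfinite(rt)])
            if rt.size:
                st.rts[(cond, d)] = rt
    return st


def exact_multinomial_p(observed, probs, tie_tol: float = 1e-12) -> float:
    """Exact multinomial goodness-of-fit p-value for k = 4 categories.

    Enumerates every composition of N = sum(observed) into four parts
    and sums the probabilities of all outcomes no more probable than
    the observed one (with a relative tie tolerance for floating-point
    equality).  N = 0 returns 1 by convention.
    """
    obs = np.asarray(observed, dtype=int)
    p = np.asarray(probs, dtype=float)
    if obs.shape != (4,) or p.shape != (4,):
        raise ValueError("observed and probs must be 4-vectors")
    if np.any(obs < 0) or np.any(p < 0):
        raise ValueError("negative counts or probabilities")
    N = int(obs.sum())
    if N == 0:
        return 1.0
    s = p.sum()
    if s <= 0:
        raise ValueError("probabilities sum to zero")
    p = p / s

    with np.errstate(divide="ignore"):
        logp = np.log(p)

    def log_pmf(x1, x2, x3, x4):
        t = gammaln(N + 1.0)
        out = t - gammaln(x1 + 1.0) - gammaln(x2 + 1.0) - gammaln(x3 + 1.0) - gammaln(x4 + 1.0)
        for x, lp in zip((x1, x2, x3, x4), logp):
            if np.isneginf(lp):  # zero-probability category
                out = out + np.where(np.asarray(x) > 0, -np.inf, 0.0)
            else:
                out = out + np.asarray(x) * lp
        return out

    lp0 = float(log_pmf(*(float(v) for v in obs)))
    cutoff = lp0 + math.log1p(tie_tol)

    total = 0.0
    for x1 in range(N + 1):
        rem = N - x1
        x2 = np.arange(rem + 1, dtype=float)[:, None]
        x3 = np.arange(rem + 1, dtype=float)[None, :]
        mask = (x2 + x3) <= rem
        x4 = rem - x2 - x3
        lp = log_pmf(float(x1), x2, x3, np.where(mask, x4, 0.0))
        sel = mask & (lp <= cutoff)
        if np.any(sel):
            total += float(np.exp(lp[sel]).sum())
    return min(1.0, total)


def ks2_statistic(sample_a, sample_b) -> float:
    """Scaled two-sample KS statistic D = sup|F1 - F2| * sqrt(nm/(n+m))."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("KS statistic undefined for empty samples")
    allv = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, allv, side="right") / n
    cdf_b = np.searchsorted(b, allv, side="right") / m
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    return d * math.sqrt(n * m / (n + m))


def ks2_probability(D: float, term_tol: float = 1e-12) -> float:
    """Probability that two samples share a distribution (Brownian bridge).

    This is the survival function of the Kolmogorov statistic; the
    cumulative part is evaluated with the theta-function series
    sqrt(2*pi)/D * sum_k exp(-(2k-1)^2 pi^2 / (8 D^2)) for small D and
    with the alternating series 2 * sum_k (-1)^(k-1) exp(-2 k^2 D^2)
    for large D, each truncated when terms drop below ``term_tol``.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if D < 1e-10:
        return 1.0
    if D < 1.18:
        # CDF via theta-function series, rapidly convergent for small D
        c = 0.0
        k = 1
        pref = math.sqrt(2.0 * math.pi) / D
        while True:
            term = math.exp(-((2 * k - 1) ** 2) * math.pi**2 / (8.0 * D * D))
            c += term
            if pref * term < term_tol or k > 200:
                break
            k += 1
        p = 1.0 - pref * c
    else:
        p = 0.0
        k = 1
        sign = 1.0
        while True:
            term = math.exp(-2.0 * k * k * D * D)
            p += sign * 2.0 * term
            if 2.0 * term < term_tol or k > 200:
                break
            sign = -sign
            k += 1
    return min(1.0, max(0.0, p))


def _floored_probs(sim_counts: np.ndarray, n_sim: int) -> np.ndarray:
    """Simulated decision rates floored at 1/(2 n_sim), renormalized."""
    n_resp = sim_counts.sum()
    p = sim_counts / n_resp if n_resp > 0 else np.zeros(4)
    p = np.maximum(p, 1.0 / (2.0 * max(n_sim, 1)))
    return p / p.sum()


def log_likelihood(
    subject: SummaryStats, simulated: SummaryStats, min_ks_cell: int = MIN_KS_CELL
) -> float:
    """Composite log-likelihood of subject summaries under simulated ones."""
    total = 0.0
    for cond in subject.conditions():
        if cond not in simulated.counts:
            raise ValueError(f"condition {cond!r} missing from simulation")
        probs = _floored_probs(
            simulated.counts[cond].astype(float), simulated.n_total[cond]
        )
        obs = subject.counts[cond]
        N = int(obs.sum())
        if N > 0:
            lp = gammaln(N + 1.0) - gammaln(obs + 1.0).sum() + float(
                np.sum(obs * np.log(probs))
            )
            total += lp
        for dec in DECISIONS:
            key = (cond, dec)
            rt_s = subject.rts.get(key)
            rt_m = simulated.rts.get(key)
            if rt_s is None or rt_m is None:
                continue
            if rt_s.size < min_ks_cell or rt_m.size < min_ks_cell:
                continue
            p = ks2_probability(ks2_statistic(rt_m, rt_s))
            total += math.log(max(p, 1e-300))
    return float(total)


def simulate_summary(
    params: FittedParams,
    n_per_condition: int = 1024,
    rng_seed: int | None = None,
    dt: float = 0.5,
    noise_stride: int | None = None,
) -> SummaryStats:
    """Simulate trials of each condition directly into summary statistics.

    Equivalent to ``summarize(simulate_dataset(...))`` but without
    materializing per-trial records; used inside the sampler where the
    likelihood is re-evaluated tens of thousands of times.
    """
    from .task import _rule1_start, simulate_condition

    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.spawn(len(MODELED_CONDITIONS) + 1)
    rng = np.random.default_rng(seeds[-1])
    prepared = _rule1_start(params.canonical())
    st = SummaryStats()
    for cond, seed in zip(MODELED_CONDITIONS, seeds):
        pools, rts, _ = simulate_condition(
            cond,
            params,
            n_per_condition,
            seed.generate_state(1)[0],
            dt=dt,
            noise_stride=noise_stride,
            _prepared=prepared,
        )
        # map pools onto response labels given random per-trial digits:
        # pool 1/2 -> parity of the upper digit / its opposite,
        # pool 3/4 -> magnitude class of the lower digit / its opposite
        par = rng.integers(0, 2, size=n_per_condition)  # 0 odd, 1 even
        mag = rng.integers(0, 2, size=n_per_condition)  # 0 gt5, 1 lt5
        label = np.full(n_per_condition, -1)
        label[pools == 1] = par[pools == 1]
        label[pools == 2] = 1 - par[pools == 2]
        label[pools == 3] = 2 + mag[pools == 3]
        label[pools == 4] = 2 + (1 - mag[pools == 4])
        counts = np.array([(label == i).sum() for i in range(4)], dtype=int)
        st.counts[cond] = counts
        st.n_none[cond] = int((pools == 0).sum())
        st.n_total[cond] = n_per_condition
        for i, dec in enumerate(DECISIONS):
            cell = rts[label == i]
            cell = np.sort(cell[np.isfinite(cell)])
            if cell.size:
                st.rts[(cond, dec)] = cell
    return st


def log_posterior(
    params: FittedParams,
    subject: SummaryStats,
    priors: Priors | None = None,
    n_sim: int = 1024,
    rng_seed: int | None = None,
    dt: float = 0.5,
    noise_stride: int | None = None,
) -> float:
    """Unnormalized log-posterior: simulate, score, add the shrinkage prior."""
    priors = priors or Priors()
    sim = simulate_summary(
        params, n_sim, rng_seed=rng_seed, dt=dt, noise_stride=noise_stride
    )
    ll = log_likelihood(subject, sim)
    return ll + priors.log_density(params.to_array())
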