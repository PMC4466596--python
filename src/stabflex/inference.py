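"""Pseudo-marginal Metropolis-Hastings fitting and model assessment.

The posterior over the 13 subject parameters is sampled with a random-
walk Metropolis-Hastings chain whose likelihood is estimated by fresh
simulation of the behavioral experiment at every proposal (pseudo-
marginal scheme).  MAP estimates are read off kernel-density smoothed
marginals of the pooled post-burn-in chains, and fit quality is
assessed with exact multinomial tests on the decision distributions
plus two-sample Kolmogorov-Smirnov tests on the reaction-time
distributions per (condition, decision) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, FittedParams, Priors
from .stats import (
    SummaryStats,
    exact_multinomial_p,
    ks2_probability,
    ks2_statistic,
    log_likelihood,
    simulate_summary,
)
from .task import DECISIONS

__all__ = [
    "Chain",
    "PosteriorSummary",
    "metropolis_hastings",
    "combine_and_burn",
    "map_estimate",
    "goodness_of_fit",
]


@dataclass
class Chain:
    """One Metropolis-Hastings chain over the 13-parameter vector."""

    samples: np.ndarray  # (n_steps, 13)
    log_post: np.ndarray  # (n_steps,)
    n_accepted: int
    seed: int
    burn_in: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(len(self.samples), 1)


@dataclass
class PosteriorSummary:
    """Marginal posterior densities, MAP vector and per-marginal FWHM."""

    map: FittedParams
    fwhm: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    densities: dict = field(default_factory=dict)


def metropolis_hastings(
    subject: SummaryStats,
    priors: Priors | None = None,
    n_steps: int = 20000,
    sigma_mh: float = 0.01,
    n_sim: int = 256,
    rng_seed: int = 0,
    start: FittedParams | None = None,
    dt: float = 0.5,
    noise_stride: int | None = None,
    noise_mode: str = "fresh",
    log_posterior_fn=None,
) -> Chain:
    """Random-walk MH with isotropic Gaussian proposals on all parameters.

    ``noise_mode="fresh"`` redraws the simulation noise at every
    likelihood evaluation (pseudo-marginal; the current state keeps its
    stored estimate).  ``noise_mode="crn"`` evaluates every proposal
    with common random numbers (one fixed simulation seed per chain),
    turning the noisy surface into a fixed one -- a variance-reduction
    option that mixes faster at reduced simulation budgets.

    ``log_posterior_fn(theta_vector, eval_seed)`` can be injected for
    testing (e.g. a constant to sample the prior).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    priors = priors or Priors()
    rng = np.random.default_rng(rng_seed)
    crn_seed = int(rng.integers(2**31)) if noise_mode == "crn" else None

    if log_posterior_fn is None:

        def log_posterior_fn(theta_vec, eval_seed):
            params = FittedParams.from_array(theta_vec)
            sim = simulate_summary(
                params, n_sim, rng_seed=eval_seed, dt=dt, noise_stride=noise_stride
            )
            return log_likelihood(subject, sim) + priors.log_density(theta_vec)

    theta = (start or FittedParams.from_array(priors.mu)).to_array()
    samples = np.empty((n_steps, 13))
    log_post = np.empty(n_steps)

    def eval_seed():
        return crn_seed if crn_seed is not None else int(rng.integers(2**31))

    current_lp = log_posterior_fn(theta, eval_seed())
    n_accepted = 0
    for i in range(n_steps):
        prop = theta + sigma_mh * rng.standard_normal(13)
        prop_lp = log_posterior_fn(prop, eval_seed())
        if np.log(rng.random()) < prop_lp - current_lp:
            theta, current_lp = prop, prop_lp
            n_accepted += 1
        samples[i] = theta
        log_post[i] = current_lp
    if n_steps >= 10000 and n_accepted == 0:
        warnings.warn(
            "chain accepted no proposals; check parameter scales and n_sim",
            stacklevel=2,
        )
    return Chain(samples=samples, log_post=log_post, n_accepted=n_accepted, seed=rng_seed)


def combine_and_burn(chains, burn_in: int) -> np.ndarray:
    """Drop ``burn_in`` steps per chain and concatenate the remainders."""
    kept = []
    dim = None
    for ch in chains:
        s = ch.samples if isinstance(ch, Chain) else np.asarray(ch)
        if dim is None:
            dim = s.shape[1]
        elif s.shape[1] != dim:
            raise ValueError("chains have inconsistent dimensionality")
        kept.append(s[burn_in:])
    return np.concatenate(kept, axis=0)


def _kde_marginal(x: np.ndarray, n_grid: int = 512):
    """Gaussian KDE (Silverman bandwidth) on a grid spanning range +-10%."""
    from scipy.stats import gaussian_kde

    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        grid = np.array([lo])
        dens = np.array([1.0])
        return grid, dens
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens = gaussian_kde(x, bw_method="silverman")(grid)
    return grid, dens


def _fwhm(grid: np.ndarray, dens: np.ndarray) -> float:
    if len(grid) == 1:
        return 0.0
    k = int(np.argmax(dens))
    half = dens[k] / 2.0
    left = grid[0]
    for i in range(k, -1, -1):
        if dens[i] < half:
            # linear interpolation between i and i+1
            w = (half - dens[i]) / (dens[i + 1] - dens[i])
            left = grid[i] + w * (grid[i + 1] - grid[i])
            break
    right = grid[-1]
    for i in range(k, len(grid)):
        if dens[i] < half:
            w = (half - dens[i]) / (dens[i - 1] - dens[i])
            right = grid[i] - w * (grid[i] - grid[i - 1])
            break
    return float(right - left)


def map_estimate(pooled: np.ndarray, n_grid: int = 512) -> PosteriorSummary:
    """Per-marginal KDE argmax (MAP) and full width at half maximum."""
    pooled = np.asarray(pooled)
    if pooled.ndim != 2 or pooled.shape[1] != 13:
        raise ValueError("pooled samples must be (n, 13)")
    if len(pooled) < 1000:
        raise ValueError("need at least 1000 pooled samples for a MAP estimate")
    out = PosteriorSummary(map=None)
    map_vec = np.empty(13)
    for j, name in enumerate(PARAM_NAMES):
        grid, dens = _kde_marginal(pooled[:, j], n_grid)
        map_vec[j] = grid[int(np.argmax(dens))]
        out.grids[name] = grid
        out.densities[name] = dens
        out.fwhm[name] = _fwhm(grid, dens)
    out.map = FittedParams.from_array(map_vec)
    return out


def goodness_of_fit(
    subject: SummaryStats,
    map_params: FittedParams,
    n_sim: int = 1024,
    rng_seed: int = 0,
    dt: float = 0.5,
    noise_stride: int | None = None,
    min_ks_cell: int = 3,
) -> pd.DataFrame:
    """Battery of p-values assessing the fit at ``map_params``.

    One exact multinomial test per condition on the decision counts
    (probabilities from an ``n_sim``-trial simulation) plus one
    two-sample KS test per (condition, decision) cell with at least
    ``min_ks_cell`` reaction times on both sides.  Returns a DataFrame
    with columns (test, condition, decision, p).
    """
    sim = simulate_summary(
        map_params, n_sim, rng_seed=rng_seed, dt=dt, noise_stride=noise_stride
    )
    rows = []
    for cond in subject.conditions():
        if cond not in sim.counts:
            raise ValueError(f"condition {cond!r} missing from simulation")
        sim_counts = sim.counts[cond].astype(float)
        n_resp = sim_counts.sum()
        probs = sim_counts / n_resp if n_resp > 0 else np.full(4, 0.25)
        p = exact_multinomial_p(subject.counts[cond], probs)
        rows.append(dict(test="multinomial", condition=cond, decision="", p=p))
        for dec in DECISIONS:
            rt_s = subject.rts.get((cond, dec))
            rt_m = sim.rts.get((cond, dec))
            if rt_s is None or rt_m is None:
                continue
            if rt_s.size < min_ks_cell or rt_m.size < min_ks_cell:
                continue
            p = ks2_probability(ks2_statistic(rt_m, rt_s))
            rows.append(dict(test="ks2", condition=cond, decision=dec, p=p))
    return pd.DataFrame(rows, columns=["test", "condition", "decision", "p"])
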