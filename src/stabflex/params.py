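"""The 13-dimensional subject-specific parameter vector and its priors."""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["FittedParams", "Priors", "PARAM_NAMES", "reference_subject"]

PARAM_NAMES = (
    "s_NMDA",
    "s_GABA",
    "I1_base",
    "D11",
    "D12",
    "Ibar_dist",
    "dI_dist",
    "Ibar_switch",
    "dI_switch",
    "c_plus",
    "sigma_rule",
    "sigma_decision",
    "beta",
)


@dataclass(frozen=True)
class FittedParams:
    """Free parameters fitted per subject.

    Conductance scalings (``s_NMDA``, ``s_GABA``), the condition-
    dependent rule-module inputs, the stimulus drives onto the correct
    parity/magnitude decision pools (``D11``, ``D12``), the feed-forward
    rule-to-decision weight ``c_plus``, the two noise amplitudes and the
    decision nonlinearity ``beta``.  The wrong-feature drives D21, D22
    and the input scaling alpha are fixed (0, 0, 1).
    """

    s_NMDA: float = 1.0
    s_GABA: float = 1.0
    I1_base: float = 0.0
    D11: float = 0.0
    D12: float = 0.0
    Ibar_dist: float = 0.0
    dI_dist: float = 0.0
    Ibar_switch: float = 0.0
    dI_switch: float = 0.0
    c_plus: float = 0.0
    sigma_rule: float = 0.0
    sigma_decision: float = 0.0
    beta: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, v) -> "FittedParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (13,):
            raise ValueError("parameter vector must have exactly 13 entries")
        return cls(**dict(zip(PARAM_NAMES, v.tolist())))

    def canonical(self) -> "FittedParams":
        """Absolute value of the noise amplitudes (only sigma^2 enters)."""
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        d["sigma_rule"] = abs(d["sigma_rule"])
        d["sigma_decision"] = abs(d["sigma_decision"])
        return FittedParams(**d)

    def replace(self, **kwargs) -> "FittedParams":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class Priors:
    """Independent Gaussian shrinkage priors, one (mu, sigma) per parameter.

    Defaults: mean 1 for the two conductance scalings, 0 for everything
    else; std 0.07 throughout.
    """

    mu: np.ndarray = None
    sigma: np.ndarray = None

    def __post_init__(self):
        mu = self.mu
        if mu is None:
            mu = np.zeros(13)
            mu[0] = mu[1] = 1.0
        sigma = self.sigma
        if sigma is None:
            sigma = np.full(13, 0.07)
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if mu.shape != (13,) or sigma.shape != (13,):
            raise ValueError("priors must have 13 entries")
        if np.any(sigma <= 0):
            raise ValueError("prior standard deviations must be positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    def log_density(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        z = (theta - self.mu) / self.sigma
        return float(np.sum(-0.5 * z * z - np.log(self.sigma) - 0.5 * np.log(2 * np.pi)))


def reference_subject() -> FittedParams:
    """A representative parameter set in the fitted regime.

    Chosen once to reproduce the qualitative behavioral pattern of
    trained subjects: ~95% baseline accuracy, slightly slower and
    equally accurate distractor trials, markedly slower switch trials
    (~91% correct with occasional non-responses, gated by the rule
    module's attractor transition), right-skewed reaction times, and
    per-trial rule-module energy rising from baseline through
    distractor to switch trials.
    Used as ground truth for synthetic subjects throughout the tests
    and examples.
    """
    return FittedParams(
        s_NMDA=1.0,
        s_GABA=1.0,
        I1_base=0.03,
        D11=0.09,
        D12=0.05,
        Ibar_dist=0.015,
        dI_dist=0.02,
        Ibar_switch=0.03,
        dI_switch=0.02,
        c_plus=0.035,
        sigma_rule=0.12,
        sigma_decision=0.35,
        beta=0.3,
    )
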