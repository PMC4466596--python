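"""Run configuration: YAML parameter files, presets and seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .constants import PhysioConstants
from .params import PARAM_NAMES, FittedParams, Priors

__all__ = ["RunConfig", "load_params", "save_params", "load_config", "stage_seed"]

# sampler/simulation settings at the scale the original study ran, and a
# desk-scale preset for laptop-class reproduction
PRESETS = {
    "paper": dict(
        n_steps=1_000_000,
        n_chains=2,
        burn_in=50_000,
        n_sim=1024,
        sigma_mh=0.01,
        dt=0.5,
        n_elements=50,
        penalty=1e5,
        grid_n=128,
    ),
    "desk": dict(
        n_steps=20_000,
        n_chains=2,
        burn_in=2_000,
        n_sim=256,
        sigma_mh=0.01,
        dt=2.0,
        n_elements=50,
        penalty=1e5,
        grid_n=128,
    ),
}


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    preset: str = "desk"
    seed: int = 0
    out_dir: str = "stabflex_out"
    params: FittedParams = field(default_factory=FittedParams)
    constants: PhysioConstants = field(default_factory=PhysioConstants)
    overrides: dict = field(default_factory=dict)

    @property
    def settings(self) -> dict:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; use one of {list(PRESETS)}")
        s = dict(PRESETS[self.preset])
        s.update(self.overrides)
        return s

    def hash(self) -> str:
        payload = dict(
            preset=self.preset,
            seed=self.seed,
            params=asdict(self.params),
            constants=asdict(self.constants),
            overrides=self.overrides,
        )
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31: root seed + stage counter."""
    stages = ("simulate", "fit", "landscape", "action", "bold")
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(root_seed), stages.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def load_params(path) -> FittedParams:
    """Read a FittedParams mapping from a YAML file (missing keys default)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    unknown = set(data) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in {path}: {sorted(unknown)}")
    return FittedParams(**data)


def save_params(params: FittedParams, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump({n: float(getattr(params, n)) for n in PARAM_NAMES}, f)


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML.

    Recognized top-level keys: preset, seed, out_dir, params (mapping),
    constants (mapping of physiological-constant overrides), and any
    preset-setting overrides under ``settings``.
    """
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    params = FittedParams(**(data.get("params") or {}))
    constants = PhysioConstants(**(data.get("constants") or {}))
    return RunConfig(
        preset=data.get("preset", "desk"),
        seed=int(data.get("seed", 0)),
        out_dir=data.get("out_dir", "stabflex_out"),
        params=params,
        constants=constants,
        overrides=dict(data.get("settings") or {}),
    )


def default_priors() -> Priors:
    return Priors()
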