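"""Run configuration: defaults, YAML loading, validation and seed fan-out.

A single top-level seed fans out to per-component seeds (synthetic data,
negative sampling, model initialization, evaluation trials) through a fixed
`numpy.random.SeedSequence` derivation, mirroring a two-level seed scheme:
the derivation is deterministic, so a logged config echo plus the top-level
seed reproduces a run exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "component_seed"]

_COMPONENTS = ("synth", "features", "sampling", "model", "eval")


@dataclass
class RunConfig:
    # paths
    data_dir: str = "."
    layout: dict = field(default_factory=dict)
    smiles: str | None = None
    fasta: str | None = None
    # model
    dim: int = 128
    lr: float = 1e-3
    tol: float = 1e-4
    max_epochs: int = 100
    depth: int = 1
    leaky_slope: float = 0.2
    batch_size: int | None = 32
    self_term: str = "content"
    # sampling
    threshold: float = 0.1
    ratio: int = 10
    mode: str = "uniform"
    # evaluation
    k_folds: int = 10
    n_trials: int = 10
    scenario: str = "cv"
    # global
    seed: int = 10
    deterministic: bool = True

    def validate(self) -> "RunConfig":
        if self.dim % 2:
            raise ValueError(f"dim must be even (got {self.dim})")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        return self

    def echo(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def component_seed(base_seed: int, component: str) -> int:
    """Deterministic per-component seed derived from the top-level seed."""
    if component not in _COMPONENTS:
        raise ValueError(f"unknown component {component!r}; one of {_COMPONENTS}")
    child = np.random.SeedSequence(base_seed).spawn(len(_COMPONENTS))
    return int(child[_COMPONENTS.index(component)].generate_state(1)[0] % (2 ** 31))


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Merge defaults < YAML file < explicit overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values).validate()
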