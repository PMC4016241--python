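"""Run configuration.

Every tunable of the pipeline lives in one nested dataclass tree so a YAML
file (or the CLI) can override any subset of keys.  Defaults follow the
published method: restart probability 0.7, L1 convergence 1e-6, k=5 network
neighbours, WKNN k=3, Laplace smoothing 1, equal class priors, learning
rate 0.001, 1000 GO features per sub-ontology.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .exceptions import ValidationError


@dataclass
class NetworkConfig:
    k_neighbors: int = 5
    #: logistic filter L(s) = 1/(1 + exp(c*s + d)); defaults keep s >~ 0.61
    logistic_c: float = -15.0
    logistic_d: float = math.log(9999.0)
    #: use |w| for degrees/flows so negative co-expression weights are safe
    use_abs_weights: bool = True


@dataclass
class FeatureConfig:
    n_go_features: int = 1000
    wang_w_is_a: float = 0.8
    wang_w_part_of: float = 0.6


@dataclass
class SeedConfig:
    #: balance negative seed mass against |P| + candidate-positive mass
    #: (True) or against |P| alone (False)
    balance_include_cp: bool = True


@dataclass
class PropagationConfig:
    alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    #: average integrated score over networks that contain the gene instead
    #: of always dividing by three
    mean_over_present: bool = False


@dataclass
class KnnConfig:
    k: int = 3


@dataclass
class NbConfig:
    laplace: float = 1.0


@dataclass
class SvmConfig:
    kernel: str = "linear"
    cost_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    #: slack-cost multipliers per training stratum
    level_multipliers: dict[str, float] = field(
        default_factory=lambda: {"P": 1.0, "RN": 1.0, "LP": 0.5, "LN": 0.5, "WN": 0.25}
    )
    cv_folds: int = 3


@dataclass
class EnsembleConfig:
    eta0: float = 0.001
    tol: float = 1e-6
    max_iter: int = 10000
    decay_halflife: float = 100.0


@dataclass
class EvalConfig:
    n_u_groups: int = 10
    n_folds: int = 3
    #: inner folds for soft labels; 0 means leave-one-out
    inner_folds: int = 0


@dataclass
class EPUConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: SeedConfig = field(default_factory=SeedConfig)
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    nb: NbConfig = field(default_factory=NbConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "EPUConfig":
        cfg = cls()
        for section, values in (overrides or {}).items():
            if not hasattr(cfg, section):
                raise ValidationError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            if not isinstance(values, dict):
                raise ValidationError(f"config section {section!r} must be a mapping")
            for key, val in values.items():
                if not hasattr(sub, key):
                    raise ValidationError(f"unknown config key: {section}.{key}")
                if key == "cost_grid":
                    val = tuple(float(v) for v in val)
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "EPUConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
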