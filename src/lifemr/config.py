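"""Simulation configuration: the causal diagram's path coefficients and cohort sizes.

The generative model has a childhood-BMI -> adulthood-BMI path (``gamma_child_to_adult``),
direct effects of each exposure on the outcome (``delta_child_direct``,
``delta_adult_direct``), a hidden confounder acting on both exposures and the outcome,
per-variant genetic effects partitioned into child-specific, adult-specific and shared
variants, and optional direct variant->outcome (pleiotropic) effects.  All traits are
standardised, so path coefficients are in SD/SD units (log-OR per SD for a binary
outcome).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError

RECALL_LEVELS = ("thinner", "same", "plumper")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic two-sample study.

    Defaults are the desk-scale study conditions used throughout the analyses:
    two non-overlapping cohorts of 20,000, 75 child-specific and 75 adult-specific
    variants of mean F ~ 90, a child->adult path of 0.5, no direct childhood effect
    and an adulthood direct effect of 0.6 on a quantitative outcome.
    """

    n_variants_child_specific: int = 75
    n_variants_adult_specific: int = 75
    n_variants_shared: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd_child: float = 0.11
    effect_sd_adult: float = 0.11
    shared_effect_correlation: float = 0.5
    gamma_child_to_adult: float = 0.5
    delta_child_direct: float = 0.0
    delta_adult_direct: float = 0.6
    confounder_strength: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_scope: str = "all"  # which variants carry direct outcome effects
    n_exposure_cohort: int = 20_000
    n_outcome_cohort: int = 20_000
    outcome_kind: str = "quantitative"  # or "binary"
    binary_prevalence: float = 0.1
    recall_proportions: tuple[float, float, float] = (0.32, 0.51, 0.17)
    seed: int | None = None

    # nuisance covariate effects (small, residualised away in GWAS)
    sex_effect: float = 0.05
    age_effect_per_year: float = 0.002
    n_centres: int = 5
    centre_effect_sd: float = 0.02

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_variants(self) -> int:
        return (
            self.n_variants_child_specific
            + self.n_variants_adult_specific
            + self.n_variants_shared
        )

    def validate(self) -> None:
        counts = {
            "n_variants_child_specific": self.n_variants_child_specific,
            "n_variants_adult_specific": self.n_variants_adult_specific,
            "n_variants_shared": self.n_variants_shared,
        }
        for name, v in counts.items():
            if not isinstance(v, int) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_variants <= 0:
            raise ConfigurationError("total variant count must be > 0")
        for name in ("n_exposure_cohort", "n_outcome_cohort"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0) or not (math.isfinite(lo) and math.isfinite(hi)):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        for name in (
            "effect_sd_child",
            "effect_sd_adult",
            "pleiotropy_sd",
            "confounder_strength",
            "centre_effect_sd",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v!r}")
        for name in (
            "gamma_child_to_adult",
            "delta_child_direct",
            "delta_adult_direct",
            "pleiotropy_mean",
            "sex_effect",
            "age_effect_per_year",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if not -1.0 <= self.shared_effect_correlation <= 1.0:
            raise ConfigurationError("shared_effect_correlation must lie in [-1, 1]")
        if self.outcome_kind not in ("quantitative", "binary"):
            raise ConfigurationError(f"outcome_kind must be quantitative|binary, got {self.outcome_kind!r}")
        if not 0.0 < self.binary_prevalence < 1.0:
            raise ConfigurationError("binary_prevalence must lie in (0, 1)")
        if self.pleiotropy_scope not in ("all", "shared", "child", "adult"):
            raise ConfigurationError(f"unknown pleiotropy_scope {self.pleiotropy_scope!r}")
        props = self.recall_proportions
        if len(props) != 3 or any(p <= 0 for p in props):
            raise ConfigurationError("recall_proportions must be 3 positive numbers")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("recall_proportions must sum to 1 (tolerance 1e-9)")
        if self.n_centres < 1:
            raise ConfigurationError("n_centres must be >= 1")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ConfigurationError("seed required")
        return self.seed

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["recall_proportions"] = list(self.recall_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any], strict: bool = True) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown and strict:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("maf_range", "recall_proportions"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str, strict: bool = True) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(d, strict=strict)


def substream(seed: int, stream: int):
    """A named, reproducible random substream of the master seed.

    All randomness in the package flows from the single config seed through
    numpy's SeedSequence spawning, so stages are individually reproducible.
    """
    import numpy as np

    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


# fixed substream labels (stable across versions; never renumber)
STREAM_PANEL = 0
STREAM_EFFECTS = 1
STREAM_EXPOSURE_GENO = 2
STREAM_OUTCOME_GENO = 3
STREAM_EXPOSURE_PHENO = 4
STREAM_OUTCOME_PHENO = 5
STREAM_RECALL = 6
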