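"""Simulation configuration for synthetic csTL cohorts.

The generator emulates the statistical structure of a population long-read
telomere study: crossed individual and chromosome-arm effects, batch
offsets confounded with genetic ancestry, arm-specific age slopes coupled
to arm mean length, Poisson telomeric coverage, and per-read measurement
noise.  All knobs live in :class:`SimConfig`; variance-structure knobs are
expressed as *fractions of total csTL variance* so that downstream
variance-partitioning estimates can be checked against what was put in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .arms import ARM_LABELS


class ConfigError(ValueError):
    """Raised for invalid or inconsistent simulation configuration."""


# Ordering of the 48 arms by default mean csTL, longest first.  The head and
# tail mirror the arm ranking reported for population long-read data
# (3p/4q/13q/12q long; 16q/3q/20q/12p/17p short); the middle is a fixed
# arbitrary interleaving.  Only the extremes carry scientific meaning.
_DEFAULT_ARM_ORDER: tuple[str, ...] = (
    "3p", "4q", "13q", "12q", "5p", "2p", "6p", "1q", "8q", "11p",
    "4p", "18q", "9q", "10q", "2q", "7p", "14q", "1p", "6q", "21q",
    "Xp", "5q", "15q", "8p", "13p", "22q", "10p", "18p", "9p", "11q",
    "Yq", "14p", "7q", "20p", "15p", "Xq", "21p", "19p", "22p", "17q",
    "Yp", "19q", "16p", "16q", "3q", "20q", "12p", "17p",
)


def default_arm_mean_profile(
    longest_bp: float = 5800.0, shortest_bp: float = 2300.0
) -> dict[str, float]:
    """Mean true TL per arm: a linear gradient over the default ranking."""
    n = len(_DEFAULT_ARM_ORDER)
    step = (longest_bp - shortest_bp) / (n - 1)
    return {a: longest_bp - i * step for i, a in enumerate(_DEFAULT_ARM_ORDER)}


@dataclass(frozen=True)
class BatchSpec:
    """One sequencing batch: center x platform x coverage tier.

    ``weight`` is the relative cohort share; ``ancestry_weights`` are the
    within-batch sampling probabilities for {AFR, AMR, EUR, Other}.  Setting
    a single ancestry to 1.0 reproduces the single-ancestry batches that
    confound batch with ancestry in the real cohort.
    """

    batch_id: str
    center: str
    platform: str          # "Sequel IIe", "Revio", "ONT"
    coverage_tier: str     # "high" (>25x) or "mid"
    weight: float
    ancestry_weights: Mapping[str, float] = field(
        default_factory=lambda: {"AFR": 0.5, "AMR": 0.28, "EUR": 0.13, "Other": 0.09}
    )


@dataclass(frozen=True)
class DiseaseParams:
    """Logistic disease-assignment model: logit P(case) = intercept +
    log(or_per_kb) * metric_kb + sum_c coef_c * covariate_c."""

    intercept: float
    or_per_kb: float
    metric: str = "shortest_tl"        # "shortest_tl" or "mean_tl"
    covariate_log_or: Mapping[str, float] = field(default_factory=dict)


# Batch mix loosely mirroring the PacBio batches of a ~2300-person cohort
# (weights proportional to reported batch sizes; mid-pass HudsonAlpha
# batches predominantly AFR, high-pass batches AMR-enriched).
def _default_batches() -> tuple[BatchSpec, ...]:
    mix_high = {"AFR": 0.27, "AMR": 0.55, "EUR": 0.10, "Other": 0.08}
    mix_afr = {"AFR": 0.92, "AMR": 0.05, "EUR": 0.02, "Other": 0.01}
    mix_eur = {"AFR": 0.27, "AMR": 0.26, "EUR": 0.28, "Other": 0.19}
    return (
        BatchSpec("BCM_Sequel2e_high", "BCM", "Sequel IIe", "high", 71, mix_high),
        BatchSpec("BI_Sequel2e_high", "BI", "Sequel IIe", "high", 77, mix_high),
        BatchSpec("UW_Sequel2e_high", "UW", "Sequel IIe", "high", 91, mix_high),
        BatchSpec("BCM_Revio_high", "BCM", "Revio", "high", 101, mix_high),
        BatchSpec("UW_Revio_high", "UW", "Revio", "high", 51, mix_high),
        BatchSpec("BI_Sequel2e_mid", "BI", "Sequel IIe", "mid", 181, mix_eur),
        BatchSpec("HA_Sequel2e_mid", "HA", "Sequel IIe", "mid", 971, mix_afr),
        BatchSpec("BI_Revio_mid", "BI", "Revio", "mid", 723, mix_eur),
        BatchSpec("HA_Revio_mid", "HA", "Revio", "mid", 46, mix_afr),
    )


#: Variance shares of total csTL variance attributed to each component in
#: the reference population analysis; the residual absorbs the remainder.
DEFAULT_VARIANCE_FRACTIONS: dict[str, float] = {
    "individual": 0.089,
    "arm": 0.091,
    "batch": 0.146,
    "age": 0.037,
    "ancestry": 0.031,
    "sex": 0.011,
    "smoking": 0.004,
    "bmi": 0.002,
}


@dataclass
class SimConfig:
    """Full specification of a synthetic csTL cohort."""

    n_individuals: int = 500
    age_range: tuple[float, float] = (17.0, 90.0)
    age_mean: float = 47.0
    age_sd: float = 16.0
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS)
    )
    total_sd: float = 1500.0
    arm_mean_profile: dict[str, float] = field(default_factory=default_arm_mean_profile)
    age_slope_coupling: float = 1.0
    coverage_model: dict[str, float] = field(
        default_factory=lambda: {"high": 6.0, "mid": 2.5}
    )
    read_noise_sd: float = 250.0
    allele_sd: float = 250.0
    min_reads_per_cluster: dict[str, int] = field(
        default_factory=lambda: {"high": 4, "mid": 3}
    )
    batch_design: Sequence[BatchSpec] = field(default_factory=_default_batches)
    disease_params: dict[str, DiseaseParams] = field(
        default_factory=lambda: {
            "hypertension": DiseaseParams(-0.75, 0.95),
            "ihd": DiseaseParams(-2.5, 0.97),
            "hf": DiseaseParams(-3.0, 0.97),
            "t2d": DiseaseParams(-2.0, 1.03),
        }
    )
    female_fraction: float = 0.648
    ever_smoker_fraction: float = 0.356
    bmi_mean: float = 31.0
    bmi_sd: float = 7.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fr = self.variance_fractions
        if any(v < 0 for v in fr.values()):
            raise ConfigError("variance fractions must be non-negative")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ConfigError(
                f"variance fractions sum to {sum(fr.values()):.3f} > 1"
            )
        missing = set(ARM_LABELS) - set(self.arm_mean_profile)
        if missing:
            raise ConfigError(f"arm_mean_profile missing arms: {sorted(missing)}")
        if any(r < 0 for r in self.coverage_model.values()):
            raise ConfigError("coverage rates must be >= 0")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must be (min, max) with min < max")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - sum(self.variance_fractions.values())

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["batch_design"] = [dataclasses.asdict(b) for b in self.batch_design]
        d["disease_params"] = {
            k: dataclasses.asdict(v) for k, v in self.disease_params.items()
        }
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "batch_design" in d:
            d["batch_design"] = tuple(
                b if isinstance(b, BatchSpec) else BatchSpec(**b)
                for b in d["batch_design"]
            )
        if "disease_params" in d:
            d["disease_params"] = {
                k: v if isinstance(v, DiseaseParams) else DiseaseParams(**v)
                for k, v in d["disease_params"].items()
            }
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
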