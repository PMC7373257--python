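"""Configuration objects for simulation, QC, and genome-wide score construction.

Each config is a plain dataclass with eager validation: an invalid field raises
``ConfigError`` naming the offending field, before any computation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid field '{name}': {msg}")


# Baseline behaviour of the simulated cohort: purchase volume, meal-time means
# (minutes since midnight), traffic-light composition of the menu, survey base
# rates, and the negative-binomial dispersion of item counts.
DEFAULT_BASELINE_RATES: dict = {
    "items_per_3mo": 150.0,
    "breakfast_time": 480.0,   # 08:00
    "lunch_time": 740.0,       # 12:20
    "color_probs": (0.34, 0.37, 0.29),  # green / yellow / red menu shares
    "unlabeled_prob": 0.05,
    "nb_dispersion": 8.0,
    "food_frac_breakfast": 0.25,
    "food_frac_lunch": 0.35,
    "food_frac_other": 0.10,   # remainder are beverages
    "skips_breakfast": 0.413,
    "skips_lunch": 0.345,
    "skips_dinner": 0.209,
    "prepares_breakfast_home": 0.287,
    "prepares_lunch_home": 0.096,
    "prepares_dinner_home": 0.549,
}

# Standardized effects of the true polygenic liability on each derived outcome:
# quality in Healthy Purchasing Score percentage points per SD, quantity in
# items per 3 months per SD, timing in minutes per SD, survey behaviours in
# log-odds per SD.
DEFAULT_PURCHASE_EFFECTS: dict = {
    "healthy_purchasing_score": -2.0,
    "total_items": 6.0,
    "breakfast_time": 6.0,
    "lunch_time": 2.0,
    "skips_breakfast": 0.20,
    "skips_lunch": 0.10,
    "skips_dinner": 0.05,
    "prepares_breakfast_home": -0.15,
    "prepares_lunch_home": -0.20,
    "prepares_dinner_home": -0.25,
}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    The defaults emulate a workplace cohort of regular cafeteria users with a
    polygenic BMI liability: ~150 purchases per 3-month baseline window, a
    roughly even green/yellow/red menu, and a liability that explains 14.8% of
    BMI variance.
    """

    n_participants: int = 500
    n_variants: int = 2000
    n_blocks: int = 200
    block_r2: float = 0.4
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.02
    frac_causal: float = 0.01
    bmi_h2: float = 0.148
    purchase_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PURCHASE_EFFECTS))
    baseline_rates: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    enrollment_window: tuple[str, str] = ("2016-09-01", "2018-02-28")
    seed: int = 0
    # Discovery-GWAS sample size used to perturb the true effects into the
    # simulated weight table (governs weight noise and discovery P values).
    discovery_n: int = 339_224
    missing_rate: float = 0.0
    # Variance of BMI not attributable to age/sex (genetic + residual), kg²/m⁴.
    bmi_residual_var: float = 30.0

    def __post_init__(self) -> None:
        _require(self.n_participants >= 1, "n_participants", "must be >= 1")
        _require(self.n_variants >= 1, "n_variants", "must be >= 1")
        _require(self.n_blocks >= 1, "n_blocks", "must be >= 1")
        _require(self.n_variants % self.n_blocks == 0, "n_blocks",
                 "n_variants must be divisible by n_blocks")
        _require(0.0 <= self.block_r2 <= 1.0, "block_r2", "must be in [0, 1]")
        lo, hi = self.maf_range
        _require(0.01 < lo <= hi <= 0.5,
                 "maf_range", "must satisfy 0.01 < lo <= hi <= 0.5")
        _require(self.effect_sd >= 0, "effect_sd", "must be >= 0")
        _require(0.0 <= self.frac_causal <= 1.0, "frac_causal", "must be in [0, 1]")
        _require(0.0 <= self.bmi_h2 <= 1.0, "bmi_h2", "must be in [0, 1]")
        _require(0.0 <= self.missing_rate < 1.0, "missing_rate", "must be in [0, 1)")
        _require(self.discovery_n >= 1, "discovery_n", "must be >= 1")
        _require(self.bmi_residual_var > 0, "bmi_residual_var", "must be > 0")
        rates = dict(DEFAULT_BASELINE_RATES)
        rates.update(self.baseline_rates)
        self.baseline_rates = rates
        effects = dict(DEFAULT_PURCHASE_EFFECTS)
        effects.update(self.purchase_effects)
        self.purchase_effects = effects
        probs = rates["color_probs"]
        _require(len(probs) == 3 and all(0 <= p <= 1 for p in probs)
                 and abs(sum(probs) - 1.0) < 1e-8,
                 "baseline_rates.color_probs", "must be 3 probabilities summing to 1")
        _require(0.0 <= rates["unlabeled_prob"] < 1.0,
                 "baseline_rates.unlabeled_prob", "must be in [0, 1)")
        for key in ("skips_breakfast", "skips_lunch", "skips_dinner",
                    "prepares_breakfast_home", "prepares_lunch_home",
                    "prepares_dinner_home"):
            _require(0.0 < rates[key] < 1.0, f"baseline_rates.{key}",
                     "must be a probability in (0, 1)")


@dataclass
class QcThresholds:
    """Variant- and sample-level QC cutoffs.

    Defaults: Hardy-Weinberg exact P >= 1e-6, MAF >= 0.01, variant call rate
    >= 98%, sample call rate >= 95%, heterozygosity fence median + 3*IQR,
    relatedness pi-hat <= 0.25, imputation quality >= 0.50.
    """

    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    variant_call_min: float = 0.98
    sample_call_min: float = 0.95
    het_iqr_mult: float = 3.0
    pihat_max: float = 0.25
    impq_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "variant_call_min",
                     "sample_call_min", "pihat_max", "impq_min"):
            val = getattr(self, name)
            _require(0.0 <= val <= 1.0, name, "must be in [0, 1]")
        _require(self.het_iqr_mult >= 0, "het_iqr_mult", "must be >= 0")


#: Default discovery-P threshold scan grid; a dense grid subsuming the
#: best-fit (0.19) and sensitivity (0.25, 0.50, 1.00) thresholds.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.19, 0.25, 0.5, 1.0)


@dataclass
class GpsConfig:
    """Genome-wide score construction: LD clumping window/r² and threshold grid."""

    clump_window: int = 250_000
    clump_r2: float = 0.1
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    maf_min: float = 0.01
    impq_min: float = 0.50

    def __post_init__(self) -> None:
        _require(self.clump_window > 0, "clump_window", "must be > 0")
        _require(0.0 < self.clump_r2 < 1.0, "clump_r2", "must be in (0, 1)")
        _require(len(self.thresholds) >= 1, "thresholds", "must be non-empty")
        _require(all(0.0 < t <= 1.0 for t in self.thresholds), "thresholds",
                 "each threshold must be in (0, 1]")
        _require(0.0 <= self.maf_min <= 1.0, "maf_min", "must be in [0, 1]")
        _require(0.0 <= self.impq_min <= 1.0, "impq_min", "must be in [0, 1]")
        self.thresholds = tuple(sorted(set(float(t) for t in self.thresholds)))


def _from_mapping(cls, mapping: Mapping) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown field(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("maf_range", "enrollment_window"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_yaml_config(path: str) -> dict:
    """Load a pipeline YAML config with ``simulation:``, ``qc:``, ``gps:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at the top level")
    out = {
        "simulation": _from_mapping(SimulationConfig, raw.get("simulation", {})),
        "qc": _from_mapping(QcThresholds, raw.get("qc", {})),
        "gps": _from_mapping(GpsConfig, raw.get("gps", {})),
    }
    extra = set(raw) - {"simulation", "qc", "gps"}
    if extra:
        raise ConfigError(f"unknown config section(s): {sorted(extra)}")
    return out
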