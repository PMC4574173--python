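"""Configuration dataclasses shared across the pipeline.

All knobs that govern simulation, breath processing, emission formulas and
the statistical analysis live here so that a single YAML file can reproduce
a run end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "SimulationConfig",
    "FormulaCoefficients",
    "FeedContext",
    "PipelineConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its documented range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic herd / visit / breath-gas generator.

    Defaults describe a 21-cow commercial herd milked in an automatic
    milking system (AMS), measured for 7 consecutive days: body weight
    619 +/- 14.2 kg, milk 29.1 +/- 6.5 kg/day, 14 of 21 cows primiparous,
    visits to the AMS averaging 2.54 per cow per day, gas sampled every
    15 s, and barn background at 23.2 ppm CH4 / 495.8 ppm CO2.

    The CH4:CO2 ratio is hierarchical: a log-normal cow effect
    (``cv_between``, % of the mean) times a log-normal cow-day effect
    (``cv_within``), times a cosine diurnal modulation with trough at
    04:00 (fractional amplitude ``diurnal_amplitude``).
    """

    n_cows: int = 21
    n_days: int = 7
    seed: int = 0
    # CH4:CO2 ratio structure (ppm/ppm, dimensionless)
    mean_ratio: float = 0.08
    cv_between: float = 8.4     # % of mean, cow level
    cv_within: float = 15.9     # % of mean, cow-day level
    diurnal_amplitude: float = 0.10  # fraction of the hourly mean
    # AMS visit schedule
    visit_rate: float = 2.54    # mean visits/cow/day on {1,2,3,4}
    visit_duration_min: tuple[float, float] = (4.0, 8.0)
    sample_interval_s: int = 15
    # gas levels (ppm)
    barn_ch4_ppm: float = 23.2
    barn_co2_ppm: float = 495.8
    plume_co2_mean_ppm: float = 3000.0   # breath CO2 excess above background
    plume_noise_cv: float = 30.0         # % multiplicative sample noise
    # herd covariates
    bw_mean_sd: tuple[float, float] = (619.0, 14.2)
    milk_mean_sd: tuple[float, float] = (29.1, 6.5)
    fat_pct_mean_sd: tuple[float, float] = (4.5, 0.5)
    protein_pct_mean_sd: tuple[float, float] = (3.4, 0.25)
    parity_fraction_primiparous: float = 14 / 21
    pregnancy_days_range: tuple[int, int] = (0, 200)
    # feeding
    tmr_herd_mean: float = 15.0          # kg DM/day
    concentrate_mean_sd: tuple[float, float] = (6.0, 1.5)

    def __post_init__(self) -> None:
        if self.n_cows < 2:
            raise ConfigurationError("n_cows must be >= 2")
        if self.n_days < 0:
            raise ConfigurationError("n_days must be >= 0")
        for name in ("cv_between", "cv_within", "plume_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mean_ratio <= 0:
            raise ConfigurationError("mean_ratio must be > 0")
        if self.sample_interval_s <= 0:
            raise ConfigurationError("sample_interval_s must be > 0")
        if not (1.0 <= self.visit_rate <= 4.0):
            raise ConfigurationError("visit_rate must lie in [1, 4]")
        lo, hi = self.visit_duration_min
        if not (0 < lo <= hi):
            raise ConfigurationError("visit_duration_min must be a positive (lo, hi) range")
        if not (0.0 <= self.parity_fraction_primiparous <= 1.0):
            raise ConfigurationError("parity_fraction_primiparous must lie in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FormulaCoefficients:
    """Coefficients of the literature formulas used in Steps II-III.

    Each formula is isolated so that a different variant (e.g. another
    CIGR heat-production form) can be swapped in without touching code:

    * heat production (W): ``hp_bw * BW^hp_bw_exp + hp_milk * Y + hp_preg * P^3``
    * daily CO2 (L/day): ``HP/1000 * co2_l_per_hpu_hour * 24``
    * ECM (kg/day): ``milk * (ecm_fat * fat% + ecm_protein * protein% + ecm_const) / ecm_denom``
    * EDMI (kg DM/day): ``a - substitution_rate * (c - b) + d + c``
    """

    hp_bw: float = 5.6
    hp_bw_exp: float = 0.75
    hp_milk: float = 22.0
    hp_preg: float = 1.6e-5
    co2_l_per_hpu_hour: float = 180.0
    ecm_fat: float = 0.383
    ecm_protein: float = 0.242
    ecm_const: float = 0.7832
    ecm_denom: float = 3.14
    substitution_rate: float = 0.5
    parity_correction_primiparous: float = -1.61
    parity_correction_multiparous: float = 0.39

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FormulaCoefficients":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class FeedContext:
    """Herd feeding context for the estimated dry-matter-intake formula.

    ``tmr_herd_mean`` (a) and ``concentrate_herd_mean`` (b) are herd
    averages in kg DM/day; the individual concentrate intake (c) and the
    parity correction (d; -1.61 first lactation, +0.39 later lactations)
    come from the cow table at evaluation time.
    """

    tmr_herd_mean: float
    concentrate_herd_mean: float
    substitution_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.tmr_herd_mean < 0 or self.concentrate_herd_mean < 0:
            raise ConfigurationError("herd intakes must be >= 0")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ConfigurationError("substitution_rate must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (the YAML surface of the CLI)."""

    out_dir: Path = Path("bovigas_out")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # breath processing
    co2_threshold_ppm: float = 400.0
    background_mode: Literal["period", "day"] = "period"
    ratio_aggregation: Literal["mean-of-ratios", "ratio-of-means"] = "mean-of-ratios"
    # emission model
    ecm_reference: float = 30.0
    coefficients: FormulaCoefficients = field(default_factory=FormulaCoefficients)
    # statistics
    alpha: float = 0.05
    r2_mode: Literal["cow-random", "year-random"] = "cow-random"
    responses: tuple[str, ...] = ("ch4_l_day", "ch4_per_edmi", "ch4_per_ecm", "ratio")
    # two-year simulation
    two_year: bool = True
    year_correlation: float = 0.7
    make_plots: bool = False
    dry_run: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.co2_threshold_ppm <= 0:
            raise ConfigurationError("co2_threshold_ppm must be > 0")
        if self.ecm_reference <= 0:
            raise ConfigurationError("ecm_reference must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            for key in ("visit_duration_min", "bw_mean_sd", "milk_mean_sd",
                        "fat_pct_mean_sd", "protein_pct_mean_sd",
                        "pregnancy_days_range", "concentrate_mean_sd"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        if "coefficients" in raw:
            raw["coefficients"] = FormulaCoefficients(**raw["coefficients"])
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d
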