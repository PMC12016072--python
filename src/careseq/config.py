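"""Configuration objects for the generator and the end-to-end pipeline.

All tunable study parameters (observation window, test-strip threshold,
hospital-outpatient rule, candidate cluster range, normalization variant)
live here with the defaults of the pediatric type 1 diabetes care-pathway
analysis the package implements. Configs are plain dataclasses validated in
``__post_init__``; YAML round-tripping is provided for shell use.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration field is out of its valid domain."""


def _check_probability(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and 0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be a probability in [0, 1], got {value!r}")


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigurationError(f"invalid ISO date: {value!r}") from exc


def quarter_aligned(window: tuple[date, date]) -> bool:
    """True if ``window`` = (start, inclusive end) covers whole calendar quarters."""
    start, end = window
    end_excl = end + timedelta(days=1)
    return (
        start.day == 1
        and start.month in (1, 4, 7, 10)
        and end_excl.day == 1
        and end_excl.month in (1, 4, 7, 10)
    )


@dataclass(frozen=True)
class ArchetypeRates:
    """Per-interval event probabilities for one care archetype.

    ``contact``, ``hba1c`` and ``strips`` are per-quarter Bernoulli rates
    (the strips rate is the probability of a prescription totalling at least
    the threshold quantity in the quarter); ``retinopathy``, ``cholesterol``
    and ``thyroid`` are per-year screening rates.
    """

    contact: float
    hba1c: float
    strips: float
    retinopathy: float
    cholesterol: float
    thyroid: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            _check_probability(f.name, getattr(self, f.name))


#: Quarterly/annual event rates of the guideline-adherent archetype. The
#: study reports ~95% of quarters with an outpatient contact, ~85% of
#: quarters with an HbA1c state and ~80% of years with >=2 screenings in
#: this group; the per-event rates below reproduce those margins.
ADHERENT_RATES = ArchetypeRates(
    contact=0.96, hba1c=0.85, strips=0.65,
    retinopathy=0.75, cholesterol=0.75, thyroid=0.75,
)

#: Rates of the care-with-gaps archetype: HbA1c in ~35% of quarters and
#: ~70% of years with at most one screening.
GAPS_RATES = ArchetypeRates(
    contact=0.90, hba1c=0.35, strips=0.35,
    retinopathy=0.30, cholesterol=0.30, thyroid=0.30,
)

#: Log-odds contributions of covariates to adherent-archetype membership
#: (natural logs of the odds ratios reported for the cohort: 0.875 per birth
#: year, 2.428 for DMP enrollment, 1.695 for autoimmune comorbidity, 1.387
#: for parental Abitur, 0.433 for parental unemployment).
DEFAULT_SES_LOGIT = {
    "birth_year_centered": math.log(0.875),
    "dmp_enrolled": math.log(2.428),
    "comorbidity_autoimmune": math.log(1.695),
    "education_abitur": math.log(1.387),
    "unemployed": math.log(0.433),
}

#: Cohort-wide covariate marginals (proportions) used by the generator.
DEFAULT_COVARIATE_PREVALENCE = {
    "birth_year": {2003: 0.279, 2004: 0.274, 2005: 0.230, 2006: 0.217},
    "sex_female": 0.480,
    "dmp_enrolled": 0.478,
    "comorbidity_autoimmune": 0.142,
    "comorbidity_asthma": 0.092,
    "comorbidity_psychological": 0.306,
    "comorbidity_cardiovascular": 0.104,
    "education_abitur": 0.449,
    "university_degree": 0.319,
    "job_type": {
        "unskilled": 0.072,
        "specialist": 0.450,
        "complex_specialist": 0.195,
        "highly_complex": 0.283,
    },
    "unemployed": 0.051,
    "migration_history": 0.059,
    "district_type": {
        "large_city": 0.246,
        "urban": 0.474,
        "rural_agglomeration": 0.141,
        "sparse": 0.139,
    },
}

#: Parental SES fields that go missing jointly for a missing-SES patient.
SES_FIELDS = (
    "education_abitur",
    "university_degree",
    "job_type",
    "unemployed",
    "migration_history",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic claims-table generator.

    The defaults plant the study's statistical structure: a 75/25
    adherent/care-with-gaps mixture whose membership follows a logistic
    model of SES covariates, archetype-specific quarterly and annual event
    rates, Poisson hospitalization counts with means 1.11 vs 1.54 per three
    years, and jointly-missing parental SES in 16% of patients.
    """

    n_patients: int = 900
    mixture_proportion_adherent: float = 0.75
    rates_adherent: ArchetypeRates = ADHERENT_RATES
    rates_gaps: ArchetypeRates = GAPS_RATES
    ses_logit_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SES_LOGIT)
    )
    hosp_rate_adherent: float = 1.11
    hosp_rate_gaps: float = 1.54
    ses_missing_rate: float = 0.16
    observation_window: tuple[date, date] = (date(2017, 1, 1), date(2019, 12, 31))
    lookback_year: int = 2016
    birth_year_window: tuple[int, int] = (2003, 2006)
    # probability that a quarter without a qualifying strips event still
    # carries a sub-threshold prescription row (quantity in [50, 199])
    strips_subthreshold_rate: float = 0.10
    strips_threshold: int = 200
    hospital_outpatient_fraction: float = 0.0
    covariate_prevalence: Mapping = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_patients, int) and self.n_patients > 0):
            raise ConfigurationError(
                f"n_patients must be a positive integer, got {self.n_patients!r}"
            )
        if not (0.0 < self.mixture_proportion_adherent <= 1.0):
            raise ConfigurationError(
                "mixture_proportion_adherent must lie in (0, 1], got "
                f"{self.mixture_proportion_adherent!r}"
            )
        for name in ("ses_missing_rate", "strips_subthreshold_rate",
                     "hospital_outpatient_fraction"):
            _check_probability(name, getattr(self, name))
        for name in ("hosp_rate_adherent", "hosp_rate_gaps"):
            value = getattr(self, name)
            if not value >= 0:
                raise ConfigurationError(f"{name} must be a nonnegative Poisson mean")
        start, end = (_parse_date(d) for d in self.observation_window)
        if start > end:
            raise ConfigurationError("observation_window start is after its end")
        object.__setattr__(self, "observation_window", (start, end))
        if not quarter_aligned(self.observation_window):
            raise ConfigurationError("observation_window must cover whole calendar quarters")
        if self.strips_threshold <= 0:
            raise ConfigurationError("strips_threshold must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observation_window"] = [x.isoformat() for x in self.observation_window]
        d["rates_adherent"] = dataclasses.asdict(self.rates_adherent)
        d["rates_gaps"] = dataclasses.asdict(self.rates_gaps)
        d["covariate_prevalence"] = {
            k: dict(v) if isinstance(v, Mapping) else v
            for k, v in self.covariate_prevalence.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("rates_adherent", "rates_gaps"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = ArchetypeRates(**d[key])
        if "observation_window" in d:
            d["observation_window"] = tuple(_parse_date(x) for x in d["observation_window"])
        if "birth_year_window" in d:
            d["birth_year_window"] = tuple(int(x) for x in d["birth_year_window"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline parameters.

    Either ``input_dir`` points at a directory of claims-like CSV tables or
    ``generator`` supplies a :class:`GeneratorConfig` to simulate them.
    """

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    observation_window: tuple[date, date] = (date(2017, 1, 1), date(2019, 12, 31))
    insurance_window: tuple[date, date] = (date(2016, 1, 1), date(2019, 12, 31))
    lookback_year: int = 2016
    birth_year_window: tuple[int, int] = (2003, 2006)
    strips_threshold: int = 200
    hospital_outpatient_min_quarters: int = 8
    k_min: int = 2
    k_max: int = 10
    normalization: str = "observed_max"
    write_matrices: bool = False
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.generator is None and self.input_dir is None:
            raise ConfigurationError("either generator or input_dir must be given")
        for name in ("strips_threshold", "hospital_outpatient_min_quarters"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (2 <= self.k_min <= self.k_max):
            raise ConfigurationError(
                f"invalid cluster range [{self.k_min}, {self.k_max}]"
            )
        if self.normalization not in ("observed_max", "observed_range", "theoretical_max"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        window = tuple(_parse_date(d) for d in self.observation_window)
        object.__setattr__(self, "observation_window", window)
        if not quarter_aligned(window):
            raise ConfigurationError("observation_window must cover whole calendar quarters")
        ins = tuple(_parse_date(d) for d in self.insurance_window)
        object.__setattr__(self, "insurance_window", ins)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observation_window"] = [x.isoformat() for x in self.observation_window]
        d["insurance_window"] = [x.isoformat() for x in self.insurance_window]
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("observation_window", "insurance_window"):
            if key in d:
                d[key] = tuple(_parse_date(x) for x in d[key])
        if "birth_year_window" in d:
            d["birth_year_window"] = tuple(int(x) for x in d["birth_year_window"])
        return cls(**d)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return PipelineConfig.from_dict(raw)


def load_generator_config(path) -> GeneratorConfig:
    """Read a generator configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return GeneratorConfig.from_dict(raw)
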