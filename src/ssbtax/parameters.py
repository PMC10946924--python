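"""Model inputs: domain types, validation, and plain-text input/output.

Every scalar the model uses lives in :class:`ParameterSet`; age/sex-resolved
epidemiology lives in :class:`EpiSchedule`; SSB consumption per IRSD quintile
lives in :class:`QuintileProfile`.  Inputs round-trip through a flat key-value
config file (one section per model stage) plus two delimited tables, so a run
is fully reproducible from text files.

Conventions
-----------
* All transition inputs are annual probabilities in [0, 1]; multi-year
  probabilities are converted with :func:`annualize_probability`
  (compounding form, never linear scaling).
* ``mean_cups_per_day`` is the mean over the whole quintile population
  (consumers and non-consumers); the share of consumers is carried separately
  for reporting and is not multiplied in again downstream.
* Costs are 2020 Australian dollars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

SEXES = ("female", "male")
MAX_AGE = 100
MIXED_DENTITION_AGES = (6, 14)


class ConfigurationError(KeyError):
    """A mandatory input key or table is missing."""


class ValidationError(ValueError):
    """An input value is outside its admissible range."""


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.0):
        raise ValidationError(f"{name} must be non-negative, got {value!r}")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuintileProfile:
    """SSB consumption and population share for one IRSD quintile.

    ``quintile_id`` is 1 (most disadvantaged) .. 5 (least disadvantaged),
    or the string ``"total"`` for the whole-population row.
    """

    quintile_id: Union[int, str]
    prop_consumers: float
    mean_cups_per_day: float
    population_share: float

    def __post_init__(self) -> None:
        if self.quintile_id != "total" and self.quintile_id not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"quintile_id must be 1-5 or 'total', got {self.quintile_id!r}"
            )
        _check_prob("prop_consumers", self.prop_consumers)
        _check_prob("population_share", self.population_share)
        _check_nonneg("mean_cups_per_day", self.mean_cups_per_day)


def validate_profiles(profiles: Iterable[QuintileProfile]) -> None:
    """Check the five quintile rows partition the population (shares sum to 1)."""
    shares = [p.population_share for p in profiles if p.quintile_id != "total"]
    if shares and abs(sum(shares) - 1.0) > 1e-9:
        raise ValidationError(
            f"quintile population shares must sum to 1, got {sum(shares)!r}"
        )


#: Columns an epidemiology table must provide, besides ``age`` and ``sex``.
EPI_COLUMNS = (
    "caries_incidence",
    "edentulism_incidence",
    "edentulism_prevalence",
    "caries_prevalence",
    "mortality",
    "deciduous_fraction",
    "p_toothache",
    "p_attend",
    "p_denture_need",
)


class EpiSchedule:
    """Age- and sex-specific annual epidemiology inputs.

    Wraps a table with one row per (age 0-100, sex in {female, male}) and the
    columns in :data:`EPI_COLUMNS`: annual caries incidence, annual edentulism
    incidence, edentulism and caries prevalence at cohort entry, background
    mortality, deciduous share of the dentition, and the three care-seeking
    probabilities (toothache given caries, 12-month dental attendance,
    perceived denture need among the edentulous).

    Internally each column is held as a dense ``(2, 101)`` array indexed by
    (sex, age), which is what the cohort engine consumes.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ("age", "sex", *EPI_COLUMNS) if c not in table.columns]
        if missing:
            raise ConfigurationError(f"epidemiology table missing columns: {missing}")
        table = table.copy()
        table["sex"] = table["sex"].astype(str)
        expected = {(a, s) for a in range(MAX_AGE + 1) for s in SEXES}
        got = set(zip(table["age"].astype(int), table["sex"]))
        if got != expected:
            absent = sorted(expected - got)[:5]
            raise ConfigurationError(
                f"epidemiology table must cover ages 0-{MAX_AGE} for both sexes; "
                f"first missing cells: {absent}"
            )
        self._arrays: dict[str, np.ndarray] = {}
        for col in EPI_COLUMNS:
            grid = np.empty((2, MAX_AGE + 1))
            for si, sex in enumerate(SEXES):
                sub = table[table["sex"] == sex].sort_values("age")
                grid[si] = sub[col].to_numpy(dtype=float)
            _check_prob(col, grid)
            self._arrays[col] = grid
        self._table = table.sort_values(["sex", "age"]).reset_index(drop=True)

    def column(self, name: str) -> np.ndarray:
        """Return the ``(2, 101)`` (sex, age) grid for one column."""
        return self._arrays[name]

    def lookup(self, name: str, age: int, sex: str) -> float:
        return float(self._arrays[name][SEXES.index(sex), age])

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpiSchedule):
            return NotImplemented
        return all(
            np.array_equal(self._arrays[c], other._arrays[c]) for c in EPI_COLUMNS
        )


@dataclass(frozen=True)
class ParameterSet:
    """Every scalar the model uses, with central value and sampling spread.

    Fields with an ``sd_*`` companion are drawn in probabilistic sensitivity
    analysis; the rest are fixed.  Central values default to the published
    Australian inputs (2020 AUD).
    """

    # intervention effect on consumption
    net_consumption_reduction: float = 0.1152   # 20% valoric tax, net of cross-price effects
    sd_net_consumption_reduction: float = 0.0962
    effectiveness_decay: float = 1.0            # retained fraction of the effect per cycle
    min_ssb_age: int = 2                        # no consumption data below this age
    grams_sugar_per_cup: float = 26.0           # free sugar per 250 mL cup

    # sugar-dose and severity
    dmft_slope_per_10g: float = 0.010           # annual DMFT change per 10 g sugar/day
    sd_dmft_slope_per_10g: float = 0.028
    teeth_per_case: float = 1.64                # decayed teeth per incident caries case
    sd_teeth_per_case: float = 1.262

    # disability
    dw_caries: float = 0.010
    sd_dw_caries: float = 0.004
    dw_edentulism: float = 0.067
    sd_dw_edentulism: float = 0.008
    caries_duration_child_days: float = 28.0    # symptomatic duration, ages 2-16
    caries_duration_adult_days: float = 55.0    # ages 17+
    adult_age_cutoff: int = 17

    # healthcare costs
    cost_checkup: float = 54.69
    sd_cost_checkup: float = 3.19
    cost_restoration: float = 189.61            # per decayed tooth restored
    sd_cost_restoration: float = 17.95
    cost_denture_pair: float = 2798.08          # full upper + lower removable dentures
    sd_cost_denture_pair: float = 433.37
    denture_survival_10y: float = 0.41
    sd_denture_survival_10y: float = 0.064
    private_care_share: float = 0.85            # informational; folded into mean fees

    # societal (time and travel) costs
    cost_travel_per_visit: float = 20.71
    time_value_per_hour: float = 49.22
    minutes_travel_per_visit: float = 60.0      # return trip
    minutes_treatment_caries: float = 60.0      # single restorative visit
    denture_visits: int = 3
    minutes_treatment_denture_total: float = 60.0  # across all denture visits

    # intervention (tax administration) costs
    intervention_cost_year1: float = 5.8e6
    sd_intervention_cost_year1: float = 0.679e6
    intervention_cost_subsequent: float = 4.47e6
    sd_intervention_cost_subsequent: float = 0.679e6

    # analysis settings
    discount_rate: float = 0.03
    wtp_per_daly: float = 50_000.0

    def __post_init__(self) -> None:
        for prob in (
            "net_consumption_reduction",
            "effectiveness_decay",
            "dw_caries",
            "dw_edentulism",
            "denture_survival_10y",
            "private_care_share",
        ):
            _check_prob(prob, getattr(self, prob))
        for nonneg in (f.name for f in fields(self)):
            _check_nonneg(nonneg, getattr(self, nonneg))

    @property
    def denture_replacement_annual(self) -> float:
        """Annual denture replacement probability from 10-year survival."""
        return annualize_probability(1.0 - self.denture_survival_10y, 10)

    def with_(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelSettings:
    """Run-level switches: horizon, arm, PSA size, seed."""

    horizon_years: int = 10                 # 10-year or lifetime (100-year) scenario
    n_psa_draws: int = 2000
    seed: int = 0
    arm: str = "intervention"
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValidationError(f"horizon_years must be >= 1, got {self.horizon_years}")
        if self.n_psa_draws < 1:
            raise ValidationError(f"n_psa_draws must be >= 1, got {self.n_psa_draws}")
        if self.arm not in ("intervention", "no_intervention"):
            raise ValidationError(f"arm must be intervention/no_intervention, got {self.arm!r}")


# --------------------------------------------------------------------------
# Probability conversion
# --------------------------------------------------------------------------

def annualize_probability(p_multi: float, years: int) -> float:
    """Convert a probability over ``years`` years to a one-year probability.

    Uses the compounding identity ``1 - (1 - p)**(1/years)``, so applying the
    annual probability independently for ``years`` cycles recovers ``p_multi``.
    """
    if not 0.0 <= p_multi <= 1.0:
        raise ValidationError(f"p_multi must lie in [0, 1], got {p_multi!r}")
    if years < 1:
        raise ValidationError(f"years must be >= 1, got {years!r}")
    return 1.0 - (1.0 - p_multi) ** (1.0 / years)


# --------------------------------------------------------------------------
# Config file I/O
# --------------------------------------------------------------------------

#: section -> fields, defining the on-disk layout of the key-value config.
_CONFIG_SECTIONS = {
    "exposure": (
        "net_consumption_reduction",
        "sd_net_consumption_reduction",
        "effectiveness_decay",
        "min_ssb_age",
        "grams_sugar_per_cup",
        "dmft_slope_per_10g",
        "sd_dmft_slope_per_10g",
    ),
    "epidemiology": (
        "teeth_per_case",
        "sd_teeth_per_case",
        "dw_caries",
        "sd_dw_caries",
        "dw_edentulism",
        "sd_dw_edentulism",
        "caries_duration_child_days",
        "caries_duration_adult_days",
        "adult_age_cutoff",
    ),
    "costs": (
        "cost_checkup",
        "sd_cost_checkup",
        "cost_restoration",
        "sd_cost_restoration",
        "cost_denture_pair",
        "sd_cost_denture_pair",
        "denture_survival_10y",
        "sd_denture_survival_10y",
        "private_care_share",
        "cost_travel_per_visit",
        "time_value_per_hour",
        "minutes_travel_per_visit",
        "minutes_treatment_caries",
        "denture_visits",
        "minutes_treatment_denture_total",
        "intervention_cost_year1",
        "sd_intervention_cost_year1",
        "intervention_cost_subsequent",
        "sd_intervention_cost_subsequent",
    ),
    "settings": (
        "discount_rate",
        "wtp_per_daly",
    ),
}

_INT_FIELDS = {"min_ssb_age", "adult_age_cutoff", "denture_visits"}

CONFIG_FILE = "parameters.ini"
EPI_FILE = "epi_schedule.csv"
QUINTILE_FILE = "quintiles.csv"


def default_parameters() -> ParameterSet:
    """The packaged central parameter values (2020 AUD)."""
    return ParameterSet()


def write_inputs(
    out_dir: Union[str, Path],
    params: ParameterSet,
    schedule: EpiSchedule,
    profiles: Iterable[QuintileProfile],
) -> Path:
    """Write a complete, reloadable input set to ``out_dir`` as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for section, keys in _CONFIG_SECTIONS.items():
        lines.append(f"[{section}]")
        for key in keys:
            val = getattr(params, key)
            lines.append(f"{key} = {val!r}" if isinstance(val, int) else f"{key} = {val:.17g}")
        lines.append("")
    (out / CONFIG_FILE).write_text("\n".join(lines))
    schedule.to_frame().to_csv(out / EPI_FILE, index=False, float_format="%.17g")
    rows = [
        {
            "quintile": p.quintile_id,
            "prop_consumers": p.prop_consumers,
            "mean_cups_per_day": p.mean_cups_per_day,
            "population_share": p.population_share,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(out / QUINTILE_FILE, index=False, float_format="%.17g")
    return out


def load_parameters(
    in_dir: Union[str, Path],
) -> tuple[ParameterSet, EpiSchedule, list[QuintileProfile]]:
    """Load and validate a full input set previously written by :func:`write_inputs`.

    Unknown config keys raise a warning; missing mandatory keys raise
    :class:`ConfigurationError`; out-of-range values raise
    :class:`ValidationError` naming the offending field.
    """
    import configparser

    in_dir = Path(in_dir)
    cfg_path = in_dir / CONFIG_FILE
    if not cfg_path.exists():
        raise ConfigurationError(f"missing config file {cfg_path}")
    cfg = configparser.ConfigParser()
    cfg.read(cfg_path)

    kwargs: dict[str, float] = {}
    for section, keys in _CONFIG_SECTIONS.items():
        if section not in cfg:
            raise ConfigurationError(f"missing config section [{section}]")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigurationError(f"missing key {key!r} in section [{section}]")
            raw = cfg[section][key]
            kwargs[key] = int(raw) if key in _INT_FIELDS else float(raw)
        for key in cfg[section]:
            if key not in keys:
                warnings.warn(f"unknown config key {key!r} in [{section}] ignored")
    params = ParameterSet(**kwargs)

    epi_path = in_dir / EPI_FILE
    if not epi_path.exists():
        raise ConfigurationError(f"missing epidemiology table {epi_path}")
    schedule = EpiSchedule(pd.read_csv(epi_path, float_precision="round_trip"))

    q_path = in_dir / QUINTILE_FILE
    if not q_path.exists():
        raise ConfigurationError(f"missing quintile table {q_path}")
    qdf = pd.read_csv(q_path, float_precision="round_trip")
    profiles = []
    for _, row in qdf.iterrows():
        qid = row["quintile"]
        qid = "total" if str(qid) == "total" else int(qid)
        profiles.append(
            QuintileProfile(
                quintile_id=qid,
                prop_consumers=float(row["prop_consumers"]),
                mean_cups_per_day=float(row["mean_cups_per_day"]),
                population_share=float(row["population_share"]),
            )
        )
    validate_profiles(profiles)
    return params, schedule, profiles
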