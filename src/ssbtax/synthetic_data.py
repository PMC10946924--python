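"""Synthetic model inputs with the statistical structure the analysis assumes.

The published analysis draws its epidemiology from national burden-of-disease
extracts and its consumption profile from a national health survey; neither
dataset is publicly deposited.  This module generates complete, internally
consistent stand-ins so every downstream stage runs and is testable offline:

* ``fixture`` mode reproduces exactly the printed quintile consumption table
  (mean daily SSB cups and share of consumers per IRSD quintile) and uses
  fixed, smooth age curves for the epidemiology — deterministic, no RNG.
* ``synthetic`` mode applies seeded random perturbations around those curves
  for property testing, preserving the shape contracts (unimodal childhood
  caries peak, zero edentulism before onset age, Gompertz-like mortality,
  strictly decreasing consumption gradient from quintile 1 to 5).

The age curves are shape-realistic, not calibrated: annual caries incidence
peaks in late childhood (~0.35) and settles near 0.1 in adulthood, edentulism
onset begins in mid-life and rises into old age, and mortality follows an
infant spike plus a Gompertz term with a modal age near 88.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ssbtax.parameters import (
    MAX_AGE,
    SEXES,
    EpiSchedule,
    QuintileProfile,
    ValidationError,
    validate_profiles,
)

#: Printed national survey values: share of SSB consumers (%) and mean daily
#: cups (whole-population mean) per IRSD quintile 1..5, plus the total row.
TABLE1_PROP_CONSUMERS = (0.447, 0.412, 0.383, 0.342, 0.290)
TABLE1_MEAN_CUPS = (1.41, 1.18, 0.94, 1.02, 0.72)
TABLE1_TOTAL = (0.372, 1.07)


@dataclass(frozen=True)
class SynthSpec:
    """Knobs for the synthetic input generator.

    ``quintile_gradient`` gives per-quintile consumption multipliers (relative
    to the total-population mean) used in synthetic mode; it must be strictly
    decreasing from quintile 1 (most disadvantaged, highest consumption) to 5.
    """

    seed: int = 0
    mode: str = "fixture"
    population_total: float = 25.7e6
    caries_incidence_peak_age: float = 12.0
    caries_incidence_peak: float = 0.35
    caries_incidence_floor: float = 0.08
    edentulism_onset_age: float = 40.0
    mortality_infant: float = 0.003
    mortality_slope: float = 0.09
    mortality_modal_age: float = 88.0
    quintile_gradient: Sequence[float] = (1.32, 1.10, 0.95, 0.88, 0.67)

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "synthetic"):
            raise ValidationError(f"mode must be fixture/synthetic, got {self.mode!r}")
        for name in ("caries_incidence_peak", "caries_incidence_floor", "mortality_infant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        g = np.asarray(self.quintile_gradient, dtype=float)
        if g.shape != (5,) or np.any(np.diff(g) >= 0):
            raise ValidationError(
                "quintile_gradient must be 5 strictly decreasing multipliers"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _unimodal_caries_curve(ages: np.ndarray, peak_age: float, peak: float,
                           floor: float) -> np.ndarray:
    # asymmetric Gaussian bump: narrow rise through childhood, slow adult decay
    width = np.where(ages < peak_age, 6.0, 30.0)
    curve = floor + (peak - floor) * np.exp(-0.5 * ((ages - peak_age) / width) ** 2)
    # few erupted teeth before age 3
    return curve * np.minimum(1.0, ages / 3.0)


def _edentulism_incidence_curve(ages: np.ndarray, onset: float) -> np.ndarray:
    curve = 0.02 / (1.0 + np.exp(-(ages - 80.0) / 8.0))
    return np.where(ages < onset, 0.0, curve)


def _edentulism_prevalence_curve(ages: np.ndarray, onset: float) -> np.ndarray:
    curve = 0.25 / (1.0 + np.exp(-(ages - 78.0) / 7.0))
    return np.where(ages < onset, 0.0, curve)


def _mortality_curve(ages: np.ndarray, infant: float, slope: float,
                     modal_age: float) -> np.ndarray:
    # infant mortality spike + Gompertz senescent hazard + small background
    hazard = (
        infant * np.exp(-ages)
        + 4e-4
        + slope * np.exp(slope * (ages - modal_age))
    )
    return np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)


def _deciduous_fraction(ages: np.ndarray) -> np.ndarray:
    lo, hi = 5.0, 15.0
    return np.clip((hi - ages) / (hi - lo), 0.0, 1.0)


def generate_epi_schedule(spec: SynthSpec) -> EpiSchedule:
    """Build a full (age 0-100, sex) epidemiology table from shape parameters.

    Identical specs produce bitwise-identical tables; in fixture mode no
    random number is ever drawn.
    """
    ages = np.arange(MAX_AGE + 1, dtype=float)

    if spec.mode == "synthetic":
        rng = spec.rng()
        caries_scale = rng.uniform(0.85, 1.15)
        peak_shift = rng.uniform(-2.0, 2.0)
        mort_scale = rng.uniform(0.9, 1.1)
        seek_scale = rng.uniform(0.9, 1.1)
    else:
        caries_scale, peak_shift, mort_scale, seek_scale = 1.0, 0.0, 1.0, 1.0

    rows = []
    for sex in SEXES:
        # mild, fixed sex contrast: females slightly lower mortality,
        # slightly higher dental attendance
        mort_sex = 0.93 if sex == "female" else 1.07
        attend_sex = 1.05 if sex == "female" else 0.95

        caries = np.clip(
            caries_scale
            * _unimodal_caries_curve(
                ages,
                spec.caries_incidence_peak_age + peak_shift,
                spec.caries_incidence_peak,
                spec.caries_incidence_floor,
            ),
            0.0,
            1.0,
        )
        edent_inc = _edentulism_incidence_curve(ages, spec.edentulism_onset_age)
        edent_prev = _edentulism_prevalence_curve(ages, spec.edentulism_onset_age)
        mortality = np.clip(
            mort_sex * mort_scale * _mortality_curve(
                ages, spec.mortality_infant, spec.mortality_slope,
                spec.mortality_modal_age,
            ),
            0.0,
            1.0,
        )
        # enforce the contract that mortality never falls beyond age 60
        tail = slice(60, None)
        mortality[tail] = np.maximum.accumulate(mortality[tail])

        p_toothache = np.full_like(ages, 0.15) * seek_scale
        p_attend = np.clip((0.55 + 0.07 * np.exp(-ages / 20.0))
                           * attend_sex * seek_scale, 0.0, 1.0)
        p_denture = np.full_like(ages, 0.30)

        # entry caries prevalence at the at-risk steady state implied by
        # incidence and treatment-driven recovery
        recovery = p_toothache + (1.0 - p_toothache) * p_attend
        caries_prev = caries / np.maximum(caries + recovery, 1e-12)

        rows.append(
            pd.DataFrame(
                {
                    "age": ages.astype(int),
                    "sex": sex,
                    "caries_incidence": caries,
                    "edentulism_incidence": edent_inc,
                    "edentulism_prevalence": edent_prev,
                    "caries_prevalence": caries_prev,
                    "mortality": mortality,
                    "deciduous_fraction": _deciduous_fraction(ages),
                    "p_toothache": np.clip(p_toothache, 0.0, 1.0),
                    "p_attend": p_attend,
                    "p_denture_need": p_denture,
                }
            )
        )
    return EpiSchedule(pd.concat(rows, ignore_index=True))


def generate_quintile_profiles(spec: SynthSpec) -> list[QuintileProfile]:
    """Quintile consumption profiles (plus a ``"total"`` row).

    Fixture mode returns the printed survey values exactly; synthetic mode
    scales the total-population mean by the spec's strictly decreasing
    gradient with a small seeded jitter that preserves the ordering.
    """
    if spec.mode == "fixture":
        profiles = [
            QuintileProfile(q + 1, TABLE1_PROP_CONSUMERS[q], TABLE1_MEAN_CUPS[q], 0.2)
            for q in range(5)
        ]
        profiles.append(QuintileProfile("total", *TABLE1_TOTAL, 1.0))
    else:
        rng = spec.rng()
        total_cups = TABLE1_TOTAL[1] * rng.uniform(0.85, 1.15)
        jitter = rng.uniform(-0.015, 0.015, size=5)
        cups = total_cups * (np.asarray(spec.quintile_gradient) + jitter)
        cons = np.clip(
            np.asarray(TABLE1_PROP_CONSUMERS) * rng.uniform(0.9, 1.1), 0.0, 1.0
        )
        profiles = [
            QuintileProfile(q + 1, float(cons[q]), float(cups[q]), 0.2)
            for q in range(5)
        ]
        profiles.append(
            QuintileProfile("total", float(cons.mean()), float(cups.mean()), 1.0)
        )
    validate_profiles(profiles)
    return profiles


def generate_population(spec: SynthSpec) -> pd.DataFrame:
    """Population counts by single year of age (0-100) and sex.

    The age shape is flat through mid-life and declines logistically in old
    age; counts sum to ``spec.population_total`` up to rounding.
    """
    ages = np.arange(MAX_AGE + 1, dtype=float)
    weight = 1.0 / (1.0 + np.exp((ages - 78.0) / 8.0))
    if spec.mode == "synthetic":
        rng = spec.rng()
        weight = weight * rng.uniform(0.9, 1.1, size=weight.shape)
    rows = []
    for sex in SEXES:
        share = 0.503 if sex == "female" else 0.497
        counts = spec.population_total * share * weight / weight.sum()
        rows.append(pd.DataFrame({"age": ages.astype(int), "sex": sex, "count": counts}))
    return pd.concat(rows, ignore_index=True)
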