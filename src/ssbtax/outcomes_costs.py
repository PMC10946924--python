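"""Traces -> decayed teeth, DALYs, and discounted costs per arm.

Health outcomes are years lived with disability only: dental caries is
nonfatal, so no years-of-life-lost term exists.  Symptomatic (toothache)
caries episodes accrue a disability weight over an age-dependent duration;
edentulism accrues its disability weight continuously over person-years.

Costs are built from treated episodes.  The healthcare perspective covers
dental fees (check-up, per-tooth restorations, denture provision and
replacement) plus, in the intervention arm, tax administration costs.  The
societal perspective adds patient travel costs and the opportunity cost of
travel and chair time — so societal = healthcare + time + travel holds as an
accounting identity per cycle.  Costs and outcomes from year 2 onward are
discounted at 3% per annum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from ssbtax.markov_engine import CycleSeries
from ssbtax.parameters import ParameterSet, ValidationError

Arr = Union[float, np.ndarray]


def _lead(x: Arr) -> np.ndarray:
    """Give a parameter (scalar or draw-axis array) a trailing cycle axis."""
    return np.asarray(x, dtype=float)[..., None]


def decayed_teeth(new_cases: Arr, teeth_per_case: Arr) -> Arr:
    """Decayed-tooth count: incident cases times mean severity (teeth/case)."""
    if np.any(np.asarray(new_cases) < 0) or np.any(np.asarray(teeth_per_case) < 0):
        raise ValidationError("new_cases and teeth_per_case must be non-negative")
    return new_cases * teeth_per_case


def caries_duration_days(age: Arr, params: ParameterSet) -> Arr:
    """Symptomatic duration: 28 days below the adult cutoff (17), else 55."""
    return np.where(
        np.asarray(age) < params.adult_age_cutoff,
        params.caries_duration_child_days,
        params.caries_duration_adult_days,
    )


def yld_caries_episode(age: Arr, params: ParameterSet) -> Arr:
    """YLD for one symptomatic caries episode at a given age."""
    return params.dw_caries * caries_duration_days(age, params) / 365.0


def yld_edentulism(person_years: Arr, dw: Arr) -> Arr:
    """YLD from edentulous person-years under a constant disability weight."""
    if np.any(np.asarray(person_years) < 0):
        raise ValidationError("person_years must be non-negative")
    return dw * person_years


def apply_care_seeking(cases: Arr, p_toothache: Arr, p_attend: Arr) -> Arr:
    """Treated caries episodes: toothache cases plus attending non-toothache cases."""
    return cases * (p_toothache + (1.0 - p_toothache) * p_attend)


def episode_costs(n_teeth: Arr, age: Arr, params: ParameterSet,
                  perspective: str) -> Arr:
    """Cost of one treated caries episode restoring ``n_teeth`` teeth.

    Healthcare: check-up fee plus per-tooth restoration fees.  Societal adds
    the return-trip travel cost and the value of travel plus chair time
    (charged identically for children, standing in for an accompanying
    adult's time).
    """
    if np.any(np.asarray(n_teeth) < 0):
        raise ValidationError("n_teeth must be non-negative")
    healthcare = params.cost_checkup + n_teeth * params.cost_restoration
    if perspective == "healthcare":
        return healthcare
    if perspective == "societal":
        extra = params.cost_travel_per_visit + params.time_value_per_hour * (
            params.minutes_travel_per_visit + params.minutes_treatment_caries
        ) / 60.0
        return healthcare + extra
    raise ValueError(f"perspective must be healthcare/societal, got {perspective!r}")


def denture_episode_cost(params: ParameterSet, perspective: str) -> Arr:
    """Cost of providing (or replacing) a pair of full dentures.

    Provision takes ``denture_visits`` appointments; treatment time totals
    ``minutes_treatment_denture_total`` across them, travel is per visit.
    """
    healthcare = np.asarray(params.cost_denture_pair, dtype=float)
    if perspective == "healthcare":
        return healthcare
    if perspective == "societal":
        extra = params.denture_visits * params.cost_travel_per_visit + (
            params.time_value_per_hour
            * (
                params.denture_visits * params.minutes_travel_per_visit
                + params.minutes_treatment_denture_total
            )
            / 60.0
        )
        return healthcare + extra
    raise ValueError(f"perspective must be healthcare/societal, got {perspective!r}")


def discount_factors(horizon: int, rate: float) -> np.ndarray:
    """Year 1 is undiscounted; year t >= 2 carries factor (1+rate)^-(t-1)."""
    if rate < 0:
        raise ValidationError("rate must be non-negative")
    t = np.arange(1, horizon + 1)
    return np.where(t == 1, 1.0, (1.0 + rate) ** -(t - 1.0))


def discount(values: np.ndarray, rate: float) -> np.ndarray:
    """Discounted total of a per-cycle series (cycle 1 first, trailing axis)."""
    values = np.asarray(values, dtype=float)
    return (values * discount_factors(values.shape[-1], rate)).sum(axis=-1)


def intervention_cost_stream(horizon: int, params: ParameterSet,
                             quintile_share: float = 1.0,
                             arm: str = "intervention") -> np.ndarray:
    """Per-cycle tax administration costs (undiscounted).

    First year carries the legislation-and-setup cost, later years the
    ongoing administration cost; quintile-level runs carry a pro-rata
    population share.  All zeros in the no-intervention arm.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    y1 = np.asarray(params.intervention_cost_year1, dtype=float)
    sub = np.asarray(params.intervention_cost_subsequent, dtype=float)
    stream = np.broadcast_to(sub[..., None], sub.shape + (horizon,)).copy()
    stream[..., 0] = y1
    if arm != "intervention":
        return np.zeros_like(stream)
    return stream * quintile_share


@dataclass
class ArmResult:
    """Discounted and undiscounted totals (and per-cycle series) for one arm.

    All arrays carry any PSA draw axis in the lead; per-cycle series have the
    cycle as the trailing axis.  ``time_travel_cost`` is the societal minus
    healthcare component, kept separate so the accounting identity
    ``societal = healthcare + time_travel`` is explicit.
    """

    horizon: int
    societal_cost_cycle: np.ndarray
    healthcare_cost_cycle: np.ndarray
    time_travel_cost_cycle: np.ndarray
    teeth_cycle: np.ndarray
    daly_cycle: np.ndarray

    total_societal_cost: np.ndarray
    total_healthcare_cost: np.ndarray
    total_decayed_teeth: np.ndarray
    total_dalys: np.ndarray
    total_societal_cost_undisc: np.ndarray
    total_healthcare_cost_undisc: np.ndarray
    total_decayed_teeth_undisc: np.ndarray
    total_dalys_undisc: np.ndarray


def arm_result_from_series(series: CycleSeries, params: ParameterSet,
                           arm: str, quintile_share: float = 1.0) -> ArmResult:
    """Price a cycle-series into the four headline accumulators."""
    T = series.horizon

    teeth = decayed_teeth(series.new_cases, _lead(params.teeth_per_case))

    treat_hc = series.treated_cases * (
        _lead(params.cost_checkup)
        + _lead(params.teeth_per_case) * _lead(params.cost_restoration)
    )
    caries_tt = params.cost_travel_per_visit + params.time_value_per_hour * (
        params.minutes_travel_per_visit + params.minutes_treatment_caries
    ) / 60.0
    treat_tt = series.treated_cases * caries_tt

    denture_episodes = series.denture_new + series.denture_wearer_py * _lead(
        annual_replacement(params)
    )
    dent_hc = denture_episodes * _lead(params.cost_denture_pair)
    dent_tt_unit = denture_episode_cost(params, "societal") - denture_episode_cost(
        params, "healthcare"
    )
    dent_tt = denture_episodes * _lead(dent_tt_unit)

    interv = intervention_cost_stream(T, params, quintile_share, arm)

    healthcare = treat_hc + dent_hc + interv
    time_travel = treat_tt + dent_tt
    societal = healthcare + time_travel

    dalys = (
        _lead(params.dw_caries)
        * (
            series.toothache_child * params.caries_duration_child_days
            + series.toothache_adult * params.caries_duration_adult_days
        )
        / 365.0
        + yld_edentulism(series.edentulous_py, _lead(params.dw_edentulism))
    )

    r = params.discount_rate
    return ArmResult(
        horizon=T,
        societal_cost_cycle=societal,
        healthcare_cost_cycle=healthcare,
        time_travel_cost_cycle=time_travel,
        teeth_cycle=teeth,
        daly_cycle=dalys,
        total_societal_cost=discount(societal, r),
        total_healthcare_cost=discount(healthcare, r),
        total_decayed_teeth=discount(teeth, r),
        total_dalys=discount(dalys, r),
        total_societal_cost_undisc=societal.sum(axis=-1),
        total_healthcare_cost_undisc=healthcare.sum(axis=-1),
        total_decayed_teeth_undisc=teeth.sum(axis=-1),
        total_dalys_undisc=dalys.sum(axis=-1),
    )


def annual_replacement(params: ParameterSet) -> Arr:
    """Annual denture replacement probability from the 10-year survival
    (compounding conversion, valid for sampled array values too)."""
    surv = np.asarray(params.denture_survival_10y, dtype=float)
    return 1.0 - surv ** (1.0 / 10.0)
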