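"""Four-state closed-cohort Markov engine.

States: caries-free, caries, edentulous, dead.  One cycle = one year.  Within
a cycle competing events are applied in a fixed order — background death
first (from every living state), then edentulism onset (from caries-free and
caries; the edentulous are no longer at risk of caries), then caries
incidence from the caries-free state (scaled by the intervention multiplier),
then treatment-driven recovery of caries back to caries-free.  Dead is
absorbing and the edentulous never re-enter a caries state.

The transition kernel broadcasts over arbitrary leading axes, so the same
code path serves a single cohort, the full (sex x age) cohort grid, and a
probabilistic-sensitivity draw axis stacked on top of the grid.  Expected
state occupancies (cohort proportions) are propagated; Monte Carlo operates
over parameters, never over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from ssbtax.parameters import (
    MAX_AGE,
    SEXES,
    EpiSchedule,
    ModelSettings,
    ParameterSet,
)

STATES = ("caries_free", "caries", "edentulous", "dead")
CARIES_FREE, CARIES, EDENTULOUS, DEAD = range(4)


class ConsistencyError(RuntimeError):
    """State occupancy stopped summing to 1 (numerical drift)."""


def care_seeking_recovery(p_toothache: np.ndarray, p_attend: np.ndarray) -> np.ndarray:
    """Fraction of caries treated (hence recovered) per cycle.

    Everyone with toothache seeks care; of the rest, those who attended a
    dentist in the last 12 months have their caries restored.
    """
    return p_toothache + (1.0 - p_toothache) * p_attend


def transition(
    state: np.ndarray,
    mortality: Union[float, np.ndarray],
    edentulism: Union[float, np.ndarray],
    caries: Union[float, np.ndarray],
    recovery: Union[float, np.ndarray],
    multiplier: Union[float, np.ndarray] = 1.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Advance occupancy one cycle; return the new state and event flows.

    ``state`` has trailing axis 4 (caries-free, caries, edentulous, dead);
    hazards broadcast against its leading axes.  Flows are per-person
    expected counts within the cycle: ``new_caries``, ``new_edentulous``,
    ``treated``, ``deaths``.
    """
    state = np.asarray(state, dtype=float)
    before = state.sum(axis=-1)
    f, c, e, d = (state[..., i] for i in range(4))

    deaths = (f + c + e) * mortality
    f1, c1, e1 = f * (1.0 - mortality), c * (1.0 - mortality), e * (1.0 - mortality)

    new_edent = (f1 + c1) * edentulism
    f2, c2 = f1 * (1.0 - edentulism), c1 * (1.0 - edentulism)
    e2 = e1 + new_edent

    new_caries = f2 * caries * multiplier
    f3, c3 = f2 - new_caries, c2 + new_caries

    treated = c3 * recovery
    out = np.stack([f3 + treated, c3 - treated, e2, d + deaths], axis=-1)

    drift = np.max(np.abs(out.sum(axis=-1) - before)) if out.size else 0.0
    if drift > 1e-8:
        raise ConsistencyError(f"occupancy sum drifted by {drift:g}")
    return out, {
        "new_caries": new_caries,
        "new_edentulous": new_edent,
        "treated": treated,
        "deaths": deaths,
    }


def initial_state(schedule: EpiSchedule, sex_idx: np.ndarray | int,
                  age: np.ndarray | int) -> np.ndarray:
    """Entry occupancy from prevalence: edentulous share first, then the
    remainder split caries / caries-free by entry caries prevalence."""
    e0 = schedule.column("edentulism_prevalence")[sex_idx, age]
    c0 = (1.0 - e0) * schedule.column("caries_prevalence")[sex_idx, age]
    return np.stack([1.0 - e0 - c0, c0, e0, np.zeros_like(e0 + 0.0)], axis=-1)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and flows for one age-sex cohort under one arm."""

    start_age: int
    sex: str
    quintile: Union[int, str]
    states: np.ndarray          # (n_cycles + 1, 4)
    new_caries_cases: np.ndarray
    new_edentulous: np.ndarray
    treated: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.states.shape[0] - 1


def n_cycles_for(start_age: int, horizon_years: int) -> int:
    """Cohorts are simulated until age 100; survivors then stop accruing."""
    return min(horizon_years, MAX_AGE + 1 - start_age)


def run_cohort(
    start_age: int,
    sex: str,
    quintile: Union[int, str],
    arm: str,
    params: ParameterSet,
    schedule: EpiSchedule,
    effect,
    settings: ModelSettings,
) -> CohortTrace:
    """Simulate one cohort; hazards are looked up at the cohort's current age."""
    if not 0 <= start_age <= MAX_AGE:
        raise ValueError(f"start_age must be 0-{MAX_AGE}, got {start_age}")
    si = SEXES.index(sex)
    mult_grid = (
        np.ones((2, MAX_AGE + 1)) if arm == "no_intervention" else effect.grid(quintile)
    )
    n = n_cycles_for(start_age, settings.horizon_years)
    states = np.empty((n + 1, 4))
    states[0] = initial_state(schedule, si, start_age)
    flows = {k: np.empty(n) for k in ("new_caries", "new_edentulous", "treated")}
    mort = schedule.column("mortality")
    edent = schedule.column("edentulism_incidence")
    car = schedule.column("caries_incidence")
    rec = care_seeking_recovery(
        schedule.column("p_toothache"), schedule.column("p_attend")
    )
    for t in range(1, n + 1):
        age = start_age + t - 1
        states[t], fl = transition(
            states[t - 1], mort[si, age], edent[si, age], car[si, age],
            rec[si, age], mult_grid[..., si, age],
        )
        for k in flows:
            flows[k][t - 1] = fl[k]
    return CohortTrace(
        start_age=start_age,
        sex=sex,
        quintile=quintile,
        states=states,
        new_caries_cases=flows["new_caries"],
        new_edentulous=flows["new_edentulous"],
        treated=flows["treated"],
    )


@dataclass
class CycleSeries:
    """Population-weighted per-cycle event totals for one arm.

    Arrays have shape ``lead + (T,)`` where ``lead`` is any draw axis carried
    by the incidence-multiplier grid; ``occupancy`` has shape
    ``lead + (T + 1, 4)``.  ``*_py`` series are person-years (half-cycle
    corrected when requested); the child/adult split of symptomatic cases is
    by current age against the adult duration cutoff.
    """

    horizon: int
    occupancy: np.ndarray
    new_cases: np.ndarray
    treated_cases: np.ndarray
    toothache_child: np.ndarray
    toothache_adult: np.ndarray
    new_edentulous: np.ndarray
    denture_new: np.ndarray
    edentulous_py: np.ndarray
    denture_wearer_py: np.ndarray


def run_population(
    arm: str,
    params: ParameterSet,
    schedule: EpiSchedule,
    population: "pd.DataFrame",
    settings: ModelSettings,
    effect=None,
    quintile: Union[int, str] = "total",
    population_share: float = 1.0,
) -> CycleSeries:
    """Run every (sex, age-0..100) cohort at once and aggregate by population.

    ``population`` is a table with columns age, sex, count covering the full
    grid; counts are multiplied by ``population_share`` for quintile-level
    runs.  The cohort grid is closed: no entrants after cycle 0.  Cohorts
    that pass age 100 are frozen and stop accruing events and person-years.
    """
    import pandas as pd  # local: keep module import light

    T = settings.horizon_years
    weights = np.zeros((2, MAX_AGE + 1))
    for _, row in population.iterrows():
        weights[SEXES.index(str(row["sex"])), int(row["age"])] = row["count"]
    weights = weights * population_share

    if arm == "no_intervention" or effect is None:
        mult_grid = np.ones((2, MAX_AGE + 1))
    else:
        mult_grid = np.asarray(effect.grid(quintile))
    lead = mult_grid.shape[:-2]

    sex_idx = np.arange(2)[:, None]
    start_age = np.arange(MAX_AGE + 1)[None, :]

    mort = schedule.column("mortality")
    edent = schedule.column("edentulism_incidence")
    car = schedule.column("caries_incidence")
    p_tooth = schedule.column("p_toothache")
    p_attend = schedule.column("p_attend")
    p_dent = schedule.column("p_denture_need")
    rec = care_seeking_recovery(p_tooth, p_attend)

    state = np.broadcast_to(
        initial_state(schedule, sex_idx, start_age), lead + (2, MAX_AGE + 1, 4)
    ).copy()

    hcc = settings.half_cycle_correction
    out = CycleSeries(
        horizon=T,
        occupancy=np.zeros(lead + (T + 1, 4)),
        new_cases=np.zeros(lead + (T,)),
        treated_cases=np.zeros(lead + (T,)),
        toothache_child=np.zeros(lead + (T,)),
        toothache_adult=np.zeros(lead + (T,)),
        new_edentulous=np.zeros(lead + (T,)),
        denture_new=np.zeros(lead + (T,)),
        edentulous_py=np.zeros(lead + (T,)),
        denture_wearer_py=np.zeros(lead + (T,)),
    )
    out.occupancy[..., 0, :] = np.einsum("...sak,sa->...k", state, weights)

    for t in range(1, T + 1):
        cur_age = start_age + t - 1                       # age during cycle t
        active = cur_age <= MAX_AGE                       # (1, 101) mask
        age_ix = np.minimum(cur_age, MAX_AGE)
        act = active.astype(float)

        new_state, fl = transition(
            state,
            mort[sex_idx, age_ix] * act,
            edent[sex_idx, age_ix] * act,
            car[sex_idx, age_ix] * act,
            rec[sex_idx, age_ix] * act,
            mult_grid[..., sex_idx, age_ix],
        )

        w_act = weights * act
        child = (cur_age < params.adult_age_cutoff).astype(float)
        tooth = p_tooth[sex_idx, age_ix]
        dent = p_dent[sex_idx, age_ix]

        ti = t - 1
        out.new_cases[..., ti] = np.einsum("...sa,sa->...", fl["new_caries"], w_act)
        out.treated_cases[..., ti] = np.einsum("...sa,sa->...", fl["treated"], w_act)
        out.toothache_child[..., ti] = np.einsum(
            "...sa,sa->...", fl["new_caries"] * tooth, w_act * child
        )
        out.toothache_adult[..., ti] = np.einsum(
            "...sa,sa->...", fl["new_caries"] * tooth, w_act * (1.0 - child)
        )
        out.new_edentulous[..., ti] = np.einsum(
            "...sa,sa->...", fl["new_edentulous"], w_act
        )
        out.denture_new[..., ti] = np.einsum(
            "...sa,sa->...", fl["new_edentulous"] * dent, w_act
        )
        e_mid = (
            0.5 * (state[..., EDENTULOUS] + new_state[..., EDENTULOUS])
            if hcc
            else new_state[..., EDENTULOUS]
        )
        out.edentulous_py[..., ti] = np.einsum("...sa,sa->...", e_mid, w_act)
        out.denture_wearer_py[..., ti] = np.einsum(
            "...sa,sa->...", e_mid * dent, w_act
        )

        state = new_state
        out.occupancy[..., t, :] = np.einsum("...sak,sa->...k", state, weights)

    return out


def cohort_traces(
    arm: str,
    params: ParameterSet,
    schedule: EpiSchedule,
    population: "pd.DataFrame",
    settings: ModelSettings,
    effect=None,
    quintile: Union[int, str] = "total",
) -> list[CohortTrace]:
    """Per-cohort traces for audit/export (same kernel as the grid run)."""
    traces = []
    for sex in SEXES:
        for age in range(MAX_AGE + 1):
            traces.append(
                run_cohort(age, sex, quintile, arm, params, schedule, effect, settings)
            )
    return traces
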