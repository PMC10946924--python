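"""Probabilistic sensitivity analysis and cost-effectiveness summaries.

Monte Carlo operates over parameters, not individuals: each draw samples one
:class:`~ssbtax.parameters.ParameterSet` realization (gamma for costs and
severity, beta for probabilities and disability weights, zero-truncated
normal for the two effect sizes), feeds the *same* realization to both arms
(common random numbers), runs the deterministic cohort engine, and records
the increments.  Cost-effectiveness is operationalized uniformly as positive
net monetary benefit, NMB = WTP x DALYs averted + cost savings, which counts
both dominant draws and draws with an ICER below the willingness-to-pay.

The draw stream is counter-based: draw ``i`` under seed ``s`` is generated
from ``SeedSequence(s, spawn_key=(i,))`` and is therefore identical across
runs, platforms, and draw-batch sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ssbtax.exposure import build_incidence_effect
from ssbtax.markov_engine import run_population
from ssbtax.outcomes_costs import ArmResult, arm_result_from_series
from ssbtax.parameters import (
    EpiSchedule,
    ModelSettings,
    ParameterSet,
    QuintileProfile,
)


class SamplingError(ValueError):
    """A parameter's (mean, sd) pair is incompatible with its distribution."""


#: field -> distribution family for PSA sampling
_GAMMA_FIELDS = (
    "teeth_per_case",
    "cost_checkup",
    "cost_restoration",
    "cost_denture_pair",
    "intervention_cost_year1",
    "intervention_cost_subsequent",
)
_BETA_FIELDS = ("dw_caries", "dw_edentulism", "denture_survival_10y")
_TRUNCNORM_FIELDS = ("net_consumption_reduction", "dmft_slope_per_10g")

SAMPLED_FIELDS = _GAMMA_FIELDS + _BETA_FIELDS + _TRUNCNORM_FIELDS


def _gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    if mean <= 0.0:
        raise SamplingError(f"gamma needs positive mean, got {mean}")
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd**2 / mean))


def _beta(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0.0:
        raise SamplingError(
            f"beta needs sd^2 < mean*(1-mean); got mean={mean}, sd={sd}"
        )
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _truncnorm0(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0.0:
        return mean
    while True:  # rejection sampling; acceptance > 50% for all used inputs
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)


def sample_draw(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One sampled realization of every uncertain parameter."""
    updates: dict[str, float] = {}
    for name in _GAMMA_FIELDS:
        updates[name] = _gamma(rng, getattr(params, name), getattr(params, "sd_" + name))
    for name in _BETA_FIELDS:
        updates[name] = _beta(rng, getattr(params, name), getattr(params, "sd_" + name))
    for name in _TRUNCNORM_FIELDS:
        updates[name] = _truncnorm0(
            rng, getattr(params, name), getattr(params, "sd_" + name)
        )
    return replace(params, **updates)


@dataclass(frozen=True)
class PSADraw:
    """One PSA realization with its provenance (seed, index)."""

    params: ParameterSet
    index: int
    seed: int


def draw_at(params: ParameterSet, seed: int, index: int) -> PSADraw:
    """The ``index``-th draw of the counter-based stream under ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
    return PSADraw(params=sample_draw(params, rng), index=index, seed=seed)


def sample_draws(params: ParameterSet, seed: int, n_draws: int) -> ParameterSet:
    """Stack ``n_draws`` counter-based draws into one array-valued ParameterSet.

    Every sampled field becomes an array of shape ``(n_draws,)``; fixed
    fields stay scalar.  The engine and costing broadcast over the axis.
    """
    draws = [draw_at(params, seed, i).params for i in range(n_draws)]
    updates = {
        name: np.array([getattr(d, name) for d in draws]) for name in SAMPLED_FIELDS
    }
    return replace(params, **updates)


# --------------------------------------------------------------------------
# Arm evaluation
# --------------------------------------------------------------------------

def run_arm(
    arm: str,
    params: ParameterSet,
    schedule: EpiSchedule,
    profiles: Sequence[QuintileProfile],
    population: pd.DataFrame,
    settings: ModelSettings,
    quintile: Union[int, str] = "total",
    decay=None,
) -> ArmResult:
    """Simulate one arm for one quintile (or the total population) and price it."""
    share = next(p.population_share for p in profiles if p.quintile_id == quintile)
    effect = build_incidence_effect(profiles, params, schedule, arm=arm, decay=decay)
    series = run_population(
        arm, params, schedule, population, settings,
        effect=effect, quintile=quintile, population_share=share,
    )
    return arm_result_from_series(series, params, arm, quintile_share=share)


# --------------------------------------------------------------------------
# Incremental analysis
# --------------------------------------------------------------------------

DOMINANT = "Dominant"
UNDEFINED = "dominated-or-undefined"


@dataclass
class Increments:
    """Per-draw increments, reported on the savings scale (positive = saving)."""

    societal_savings: np.ndarray
    healthcare_savings: np.ndarray
    teeth_averted: np.ndarray
    dalys_averted: np.ndarray
    nmb: np.ndarray
    wtp: float


def incremental_analysis(intervention: ArmResult, control: ArmResult,
                         wtp: float) -> Increments:
    """Control-minus-intervention increments and NMB at the given WTP."""
    soc = control.total_societal_cost - intervention.total_societal_cost
    hc = control.total_healthcare_cost - intervention.total_healthcare_cost
    teeth = control.total_decayed_teeth - intervention.total_decayed_teeth
    dalys = control.total_dalys - intervention.total_dalys
    return Increments(
        societal_savings=np.asarray(soc, dtype=float),
        healthcare_savings=np.asarray(hc, dtype=float),
        teeth_averted=np.asarray(teeth, dtype=float),
        dalys_averted=np.asarray(dalys, dtype=float),
        nmb=np.asarray(wtp * dalys + soc, dtype=float),
        wtp=wtp,
    )


def icer(inc: Increments) -> Union[str, float]:
    """Mean ICER: 'Dominant' when the intervention saves money and averts
    DALYs on average; otherwise incremental cost per DALY averted."""
    savings = float(np.mean(inc.societal_savings))
    dalys = float(np.mean(inc.dalys_averted))
    if savings > 0.0 and dalys > 0.0:
        return DOMINANT
    if dalys == 0.0:
        return UNDEFINED
    return -savings / dalys


def probability_cost_effective(
    inc: Increments,
    wtp: Optional[float] = None,
    wtp_grid: Optional[Sequence[float]] = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fraction of draws with positive NMB, plus a CEAC over a WTP grid.

    Returns ``(probability, grid, ceac)``; the default grid spans 0 to twice
    the analysis WTP and always contains 0 and the analysis WTP itself.
    """
    if wtp is None:
        wtp = inc.wtp
    if wtp_grid is None:
        wtp_grid = np.unique(np.r_[np.linspace(0.0, 2 * max(wtp, 1.0), 21), wtp])
    grid = np.asarray(wtp_grid, dtype=float)
    nmb_grid = grid[:, None] * inc.dalys_averted[None, ...] + inc.societal_savings
    ceac = (nmb_grid > 0).mean(axis=-1)
    prob = float((wtp * inc.dalys_averted + inc.societal_savings > 0).mean())
    return prob, grid, ceac


def _summary(values: np.ndarray) -> dict[str, float]:
    values = np.atleast_1d(values)
    return {
        "mean": float(np.mean(values)),
        "ui_low": float(np.percentile(values, 2.5)),
        "ui_high": float(np.percentile(values, 97.5)),
    }


@dataclass
class CEAResult:
    """PSA summary for one quintile (or total) at one horizon."""

    quintile: Union[int, str]
    horizon: int
    n_draws: int
    increments: Increments
    intervention: ArmResult
    control: ArmResult
    icer: Union[str, float]
    prob_cost_effective: float
    ceac_wtp: np.ndarray
    ceac: np.ndarray
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Result rows (mean and 95% UI) in the published table layout."""
        rows = [{"quantity": k, **v} for k, v in self.summaries.items()]
        return pd.DataFrame(rows)


def run_cea(
    params: ParameterSet,
    schedule: EpiSchedule,
    profiles: Sequence[QuintileProfile],
    population: pd.DataFrame,
    settings: ModelSettings,
    quintile: Union[int, str] = "total",
    decay=None,
) -> CEAResult:
    """Full PSA for one quintile: sample, run both arms per draw, summarise."""
    sampled = sample_draws(params, settings.seed, settings.n_psa_draws)
    interv = run_arm(
        "intervention", sampled, schedule, profiles, population, settings,
        quintile=quintile, decay=decay,
    )
    control = run_arm(
        "no_intervention", sampled, schedule, profiles, population, settings,
        quintile=quintile,
    )
    inc = incremental_analysis(interv, control, params.wtp_per_daly)
    prob, grid, ceac = probability_cost_effective(inc)
    summaries = {
        "total_societal_cost": _summary(control.total_societal_cost),
        "total_healthcare_cost": _summary(control.total_healthcare_cost),
        "total_decayed_teeth": _summary(control.total_decayed_teeth),
        "total_dalys": _summary(control.total_dalys),
        "societal_savings": _summary(inc.societal_savings),
        "healthcare_savings": _summary(inc.healthcare_savings),
        "teeth_averted": _summary(inc.teeth_averted),
        "dalys_averted": _summary(inc.dalys_averted),
        "nmb": _summary(inc.nmb),
    }
    return CEAResult(
        quintile=quintile,
        horizon=settings.horizon_years,
        n_draws=settings.n_psa_draws,
        increments=inc,
        intervention=interv,
        control=control,
        icer=icer(inc),
        prob_cost_effective=prob,
        ceac_wtp=grid,
        ceac=ceac,
        summaries=summaries,
    )


# --------------------------------------------------------------------------
# Threshold analysis
# --------------------------------------------------------------------------

NEVER = "never"


def threshold_effectiveness(
    params: ParameterSet,
    schedule: EpiSchedule,
    profiles: Sequence[QuintileProfile],
    population: pd.DataFrame,
    settings: ModelSettings,
    quintile: Union[int, str] = "total",
    criterion: str = "probability",
    tol: float = 1e-3,
) -> Union[float, str]:
    """Smallest retained-effectiveness fraction keeping the tax cost-effective.

    Bisects over the per-cycle effectiveness-decay constant in [0, 1] with a
    fixed draw stream (common random numbers across evaluations; the
    no-intervention arm is decay-independent and computed once).  The
    cost-effectiveness criterion is ``"probability"`` (probability of
    positive NMB >= 0.5, default) or ``"nmb"`` (mean NMB >= 0).  Returns
    ``"never"`` if the intervention is not cost-effective even at full
    effectiveness, and 0.0 if it is cost-effective with no effect at all.
    """
    if criterion not in ("probability", "nmb"):
        raise ValueError(f"criterion must be probability/nmb, got {criterion!r}")
    sampled = sample_draws(params, settings.seed, settings.n_psa_draws)
    control = run_arm(
        "no_intervention", sampled, schedule, profiles, population, settings,
        quintile=quintile,
    )

    def cost_effective(decay: float) -> bool:
        interv = run_arm(
            "intervention", sampled, schedule, profiles, population, settings,
            quintile=quintile, decay=decay,
        )
        inc = incremental_analysis(interv, control, params.wtp_per_daly)
        if criterion == "nmb":
            return float(np.mean(inc.nmb)) >= 0.0
        return float((inc.nmb > 0).mean()) >= 0.5

    if not cost_effective(1.0):
        return NEVER
    if cost_effective(0.0):
        return 0.0
    lo, hi = 0.0, 1.0  # invariant: not CE at lo, CE at hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cost_effective(mid):
            hi = mid
        else:
            lo = mid
    return hi


# --------------------------------------------------------------------------
# Equity
# --------------------------------------------------------------------------

@dataclass
class EquitySummary:
    """Quintile-1 vs quintile-5 benefit ratios and the full gradient table."""

    daly_ratio: Optional[float]
    teeth_ratio: Optional[float]
    savings_ratio: Optional[float]
    q1_dalys: float
    q5_dalys: float
    table: pd.DataFrame


def equity_summary(results: Mapping[Union[int, str], CEAResult]) -> EquitySummary:
    """Benefit gradient across IRSD quintiles (1 = most disadvantaged).

    Ratios are mean quintile-1 benefit over mean quintile-5 benefit; when the
    quintile-5 benefit is non-positive the ratio is reported as None with
    both numerators retained.
    """
    missing = [q for q in range(1, 6) if q not in results]
    if missing:
        raise ValueError(f"equity summary needs all 5 quintiles; missing {missing}")
    means = {
        q: {
            "dalys_averted": float(np.mean(results[q].increments.dalys_averted)),
            "teeth_averted": float(np.mean(results[q].increments.teeth_averted)),
            "societal_savings": float(np.mean(results[q].increments.societal_savings)),
            "healthcare_savings": float(np.mean(results[q].increments.healthcare_savings)),
        }
        for q in range(1, 6)
    }
    table = pd.DataFrame(means).T.rename_axis("quintile")

    def ratio(key: str) -> Optional[float]:
        q5 = means[5][key]
        return means[1][key] / q5 if q5 > 0 else None

    return EquitySummary(
        daly_ratio=ratio("dalys_averted"),
        teeth_ratio=ratio("teeth_averted"),
        savings_ratio=ratio("societal_savings"),
        q1_dalys=means[1]["dalys_averted"],
        q5_dalys=means[5]["dalys_averted"],
        table=table,
    )
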