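"""Tax intervention -> multiplicative reduction in annual caries incidence.

Chain: a 20% valoric SSB tax lowers consumption by a net fraction (own- and
cross-price elasticities already folded into that single number); lower cup
consumption means fewer grams of free sugar per day; the linear sugar-dose
relationship converts the gram reduction into an annual DMFT change, whose
fractional value is taken one-for-one as a fractional reduction in annual
caries incidence.  The multiplier applies identically to deciduous and
permanent dentition and is 1 below the minimum exposure age (no consumption
data for ages 0-1).

All operations broadcast over numpy arrays, so a probabilistic-sensitivity
draw axis can be threaded through ``params`` fields transparently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from ssbtax.parameters import (
    MAX_AGE,
    EpiSchedule,
    ParameterSet,
    QuintileProfile,
    ValidationError,
)

ArrayLike = Union[float, np.ndarray]


def sugar_intake(cups_per_day: ArrayLike, grams_per_cup: ArrayLike) -> ArrayLike:
    """Mean grams of free sugar per day from SSB, over the whole population."""
    if np.any(np.asarray(cups_per_day) < 0) or np.any(np.asarray(grams_per_cup) < 0):
        raise ValidationError("cups_per_day and grams_per_cup must be non-negative")
    return cups_per_day * grams_per_cup


def consumption_reduction(intake: ArrayLike, net_reduction: ArrayLike,
                          decay: ArrayLike = 1.0) -> ArrayLike:
    """Grams/day of sugar removed by the tax: intake x net effect x retained fraction."""
    for name, v in (("net_reduction", net_reduction), ("decay", decay)):
        if np.any(np.asarray(v) < 0) or np.any(np.asarray(v) > 1):
            raise ValidationError(f"{name} must lie in [0, 1]")
    return intake * net_reduction * decay


def incidence_multiplier(sugar_reduction: ArrayLike,
                         slope_per_10g: ArrayLike) -> ArrayLike:
    """Caries-incidence multiplier from a sugar reduction (grams/day).

    The fractional annual DMFT change, ``slope x reduction / 10 g``, is
    equated with the fractional incidence reduction; the multiplier is
    clamped at 0 (it never binds for the published central values).
    """
    if np.any(np.asarray(sugar_reduction) < 0):
        raise ValidationError("sugar_reduction must be non-negative")
    return np.maximum(0.0, 1.0 - slope_per_10g * sugar_reduction / 10.0)


@dataclass(frozen=True)
class IncidenceEffect:
    """Per-quintile (sex, age) grids of intervention incidence multipliers.

    ``grids[qid]`` has trailing shape ``(2, 101)``; a leading axis, if any,
    is a PSA draw axis.  All values lie in [0, 1] and equal 1 below the
    minimum exposure age.
    """

    grids: Mapping[Union[int, str], np.ndarray]

    def grid(self, quintile_id: Union[int, str]) -> np.ndarray:
        return self.grids[quintile_id]


def build_incidence_effect(
    profiles: Sequence[QuintileProfile],
    params: ParameterSet,
    schedule: EpiSchedule | None = None,
    arm: str = "intervention",
    decay: ArrayLike | None = None,
) -> IncidenceEffect:
    """Compose intake -> reduction -> multiplier per (age, sex, quintile).

    Under the no-intervention arm every multiplier is 1.  ``decay`` overrides
    ``params.effectiveness_decay`` (used by the threshold search).  ``params``
    fields may carry a leading draw axis; the returned grids then have shape
    ``(n_draws, 2, 101)``.
    """
    if decay is None:
        decay = params.effectiveness_decay
    grids: dict[Union[int, str], np.ndarray] = {}
    for prof in profiles:
        if arm == "no_intervention":
            grids[prof.quintile_id] = np.ones((2, MAX_AGE + 1))
            continue
        intake = sugar_intake(prof.mean_cups_per_day, params.grams_sugar_per_cup)
        reduction = consumption_reduction(
            intake, params.net_consumption_reduction, decay
        )
        mult = np.asarray(incidence_multiplier(reduction, params.dmft_slope_per_10g))
        grid = np.broadcast_to(
            mult[..., None, None], mult.shape + (2, MAX_AGE + 1)
        ).copy()
        ages = np.arange(MAX_AGE + 1)
        grid[..., ages < params.min_ssb_age] = 1.0
        grids[prof.quintile_id] = grid
    return IncidenceEffect(grids)
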