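"""Brute-force path-enumeration oracle for the four-state cycle kernel.

Expands the explicit within-cycle event tree (death, then edentulism onset,
then caries incidence, then treatment-driven recovery) path by path, carrying
exact branch probabilities, and aggregates expected occupancy and flows.  It
shares no code with the engine's vectorized kernel; complexity is exponential
in the number of cycles, so it is only usable on tiny instances.
"""

from __future__ import annotations

F, C, E, D = range(4)


def _branches(state: int, mort: float, edent: float, caries: float,
              recovery: float, multiplier: float):
    """Yield (next_state, probability, flows) for every within-cycle path."""
    h = caries * multiplier
    if state == D:
        yield D, 1.0, {}
        return
    yield D, mort, {"deaths": 1.0}
    live = 1.0 - mort
    if state == E:
        yield E, live, {}
        return
    # caries-free and caries states may become edentulous
    yield E, live * edent, {"new_edentulous": 1.0}
    stay = live * (1.0 - edent)
    if state == F:
        # new caries, then possibly treated within the same cycle
        yield F, stay * h * recovery, {"new_caries": 1.0, "treated": 1.0}
        yield C, stay * h * (1.0 - recovery), {"new_caries": 1.0}
        yield F, stay * (1.0 - h), {}
    else:  # prevalent caries: treated or persists
        yield F, stay * recovery, {"treated": 1.0}
        yield C, stay * (1.0 - recovery), {}


def enumerate_paths(state0, cycles):
    """Evolve an occupancy 4-vector through explicit path enumeration.

    ``cycles`` is a list of hazard dicts with keys mort, edent, caries,
    recovery, multiplier.  Returns (occupancy per cycle, flow totals per
    cycle) as plain lists of floats.
    """
    paths = [(s, p) for s, p in enumerate(state0) if p > 0.0]
    occupancies = [list(state0)]
    flow_series = []
    for hz in cycles:
        new_paths = []
        flows = {"new_caries": 0.0, "new_edentulous": 0.0, "treated": 0.0,
                 "deaths": 0.0}
        for state, prob in paths:
            for nxt, bp, fl in _branches(
                state, hz["mort"], hz["edent"], hz["caries"], hz["recovery"],
                hz.get("multiplier", 1.0),
            ):
                if bp == 0.0:
                    continue
                new_paths.append((nxt, prob * bp))
                for key, count in fl.items():
                    flows[key] += prob * bp * count
        paths = new_paths
        occ = [0.0, 0.0, 0.0, 0.0]
        for state, prob in paths:
            occ[state] += prob
        occupancies.append(occ)
        flow_series.append(flows)
    return occupancies, flow_series
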