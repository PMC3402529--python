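"""Shared fixtures: a seeded random-chart generator used by the property
suites (conservation, oracle equivalence, monotonicity)."""

from __future__ import annotations

import random

import pytest

from popchart import Influx, Region, State, Statechart, Transition, parse_guard, parse_rate


def random_chart(
    rng: random.Random,
    max_regions: int = 3,
    max_leaves: int = 4,
    with_guards: bool = True,
    with_compounds: bool = True,
    with_sinks: bool = False,
    with_influx: bool = False,
    offspring_two_prob: float = 0.0,
) -> Statechart:
    """Generate a small valid chart.

    State names are globally unique; every transition carries a declared
    parameter as its rate; guards (when enabled) are in/not-in predicates on
    states of *other* regions.
    """
    n_regions = rng.randint(1, max_regions)
    params: dict[str, float] = {}
    regions: list[Region] = []
    all_leaf_names: list[list[str]] = []
    all_state_names: list[list[str]] = []  # includes compounds, per region

    for ri in range(n_regions):
        n_leaves = rng.randint(2, max_leaves)
        leaves = [f"R{ri}S{j}" for j in range(n_leaves)]
        all_leaf_names.append(leaves)
        states: list[State]
        names = list(leaves)
        if with_compounds and n_leaves >= 3 and rng.random() < 0.5:
            # group the first k leaves into a one-level compound
            k = rng.randint(2, n_leaves - 1)
            comp = State(f"R{ri}C", tuple(State(x) for x in leaves[:k]), leaves[0])
            states = [comp] + [State(x) for x in leaves[k:]]
            names.append(f"R{ri}C")
        else:
            states = [State(x) for x in leaves]
        all_state_names.append(names)
        regions.append(Region(f"region{ri}", tuple(states), (), initial=states[0].name))

    pidx = 0
    for ri, region in enumerate(regions):
        n_trans = rng.randint(1, 4)
        transitions = []
        for _ in range(n_trans):
            src = rng.choice(all_state_names[ri])
            if with_sinks and rng.random() < 0.2:
                dst = "SINK"
            else:
                dst = rng.choice(all_state_names[ri])
            pname = f"k{pidx}"
            pidx += 1
            params[pname] = round(rng.uniform(0.05, 0.8), 3)
            guard = None
            if with_guards and n_regions >= 2 and rng.random() < 0.4:
                other = rng.choice([i for i in range(n_regions) if i != ri])
                target = rng.choice(all_state_names[other])
                guard = ("not " if rng.random() < 0.5 else "") + f"in({target})"
            offspring = 2 if rng.random() < offspring_two_prob else 1
            transitions.append(
                Transition(
                    source=src,
                    target=dst,
                    rate=parse_rate(pname),
                    guard=parse_guard(guard),
                    offspring=parse_rate(offspring),
                )
            )
        regions[ri] = Region(region.name, region.states, tuple(transitions), region.initial)

    influxes = ()
    if with_influx and rng.random() < 0.5:
        params["sigma_in"] = round(rng.uniform(0.1, 1.0), 3)
        target = rng.choice(all_state_names[0])
        influxes = (Influx(target, parse_rate("sigma_in")),)

    return Statechart(f"random_{rng.randint(0, 10**6)}", tuple(regions), params, influxes)


@pytest.fixture
def rng():
    return random.Random(20260101)
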