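"""Independent brute-force expansion oracle.

Deliberately written against the raw chart data model with plain nested
loops and name sets — it never imports popchart.expansion — so that it can
serve as a second, independent route to the product network in the
equivalence tests.  Handles simple and compound states, entry redirection,
per-substate rate overrides and conjunction guards; coupled labels are out
of its scope (they get dedicated example-based tests).
"""

from __future__ import annotations

import itertools
from collections import Counter

from popchart.model import ORIGIN, SINK, Statechart


def _leaves_under(state) -> list[str]:
    if not state.substates:
        return [state.name]
    out = []
    for c in state.substates:
        out.extend(_leaves_under(c))
    return out


def _entry(state_by_name, name: str) -> str:
    s = state_by_name[name]
    while s.substates:
        s = state_by_name[s.initial_substate]
    return s.name


def enumerate_network(chart: Statechart) -> Counter:
    """Return a Counter of (from_name, to_name, rate_source, mode) tuples,
    one per expanded flux entry, plus influx entries from EXTERNAL."""
    state_by_name = {}
    descendants = {}  # state -> set of leaf names under it
    region_idx = {}  # state name -> region position
    region_leaves = []
    for ri, r in enumerate(chart.regions):
        leaves = []
        stack = list(r.states)
        while stack:
            s = stack.pop()
            state_by_name[s.name] = s
            descendants[s.name] = set(_leaves_under(s))
            region_idx[s.name] = ri
            stack.extend(s.substates)
        for s in r.states:
            leaves.extend(_leaves_under(s))
        region_leaves.append(leaves)

    def guard_holds(guard, combo) -> bool:
        for pred in guard.predicates:
            inside = combo[region_idx[pred.state]] in descendants[pred.state]
            if inside == pred.negated:
                return False
        return True

    entries: Counter = Counter()
    combos = list(itertools.product(*region_leaves))

    for ri, r in enumerate(chart.regions):
        for t in r.transitions:
            if t.source == ORIGIN:
                continue
            src_leaves = sorted(descendants[t.source])
            for src in src_leaves:
                if isinstance(t.rate, dict):
                    # innermost override on the path src -> ... -> t.source
                    rate = None
                    name = src
                    while name != t.source and rate is None:
                        if name in t.rate:
                            rate = t.rate[name]
                        name = next(
                            p for p, s in state_by_name.items()
                            if any(c.name == name for c in s.substates)
                        )
                    rate_src = rate.source
                else:
                    rate_src = t.rate.source
                for combo in combos:
                    if combo[ri] != src:
                        continue
                    if not guard_holds(t.guard, combo):
                        continue
                    frm = "|".join(combo)
                    if t.target == SINK:
                        to = SINK
                    else:
                        tgt = _entry(state_by_name, t.target)
                        to = "|".join(
                            c if i != ri else tgt for i, c in enumerate(combo)
                        )
                    entries[(frm, to, rate_src, t.flux_mode)] += 1

    initials = [_entry(state_by_name, r.initial) for r in chart.regions]
    for ri, r in enumerate(chart.regions):
        for t in r.transitions:
            if t.source == ORIGIN:
                to = "|".join(
                    c if i != ri else _entry(state_by_name, t.target)
                    for i, c in enumerate(initials)
                )
                entries[("EXTERNAL", to, t.rate.source, "constant")] += 1
    for inf in chart.influxes:
        ri = region_idx[inf.target]
        to = "|".join(
            c if i != ri else _entry(state_by_name, inf.target)
            for i, c in enumerate(initials)
        )
        entries[("EXTERNAL", to, inf.rate.source, "constant")] += 1
    return entries
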