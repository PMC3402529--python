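"""Flattening and product expansion: the statechart → network compiler.

The compiler proceeds in two stages.  *Flattening* removes hierarchy inside
each region: a transition leaving a compound state becomes one transition per
leaf substate (carrying the substate's rate override if one is given), and a
transition entering a compound state is redirected to its initial substate,
recursively.  *Expansion* then forms the Cartesian product of the flattened
regions and emits one flux entry per (flat transition × context) pair,
applying three cross-track couplings:

* weak dependencies — rates may reference ``pop()`` of states anywhere and
  ``ind()`` indicators of other regions' coordinates (resolved per context);
* strong dependencies — guard predicates prune entries entirely: a blocked
  transition is absent from the network, not carried at rate zero;
* coupled (labelled) transitions — all members of a label move their
  coordinates in one synchronized event, and never fire individually.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .expr import GuardExpr, RateExpr, TRUE_GUARD, parse_rate
from .model import (
    ORIGIN,
    SINK,
    ChartError,
    Region,
    State,
    Statechart,
    Transition,
    require_valid,
)

__all__ = [
    "EXTERNAL",
    "FlatTransition",
    "FlatRegion",
    "ProductState",
    "FluxEntry",
    "CompiledNetwork",
    "flatten",
    "expand",
    "count_product_states",
    "MAX_PRODUCT_STATES",
]

#: Marker endpoint for constant-influx entries (no source population).
EXTERNAL = "EXTERNAL"

#: Hard cap on the expanded state space; combinatorial growth beyond desk
#: scale is rejected with a clear error rather than attempted lazily.
MAX_PRODUCT_STATES = 100_000


@dataclass(frozen=True)
class FlatTransition:
    """A leaf-to-leaf transition after hierarchy removal."""

    source: str  # leaf name or ORIGIN
    target: str  # leaf name or SINK
    rate: Optional[RateExpr]
    guard: GuardExpr
    label: Optional[str]
    offspring: RateExpr
    flux_mode: str
    provenance: str  # authored transition it instantiates


@dataclass
class FlatRegion:
    name: str
    leaves: tuple[str, ...]
    transitions: tuple[FlatTransition, ...]
    initial_leaf: str


@dataclass(frozen=True)
class ProductState:
    """One leaf state per region, region-ordered; the unit of accounting."""

    coords: tuple[str, ...]

    @property
    def name(self) -> str:
        return "|".join(self.coords)


@dataclass(frozen=True)
class FluxEntry:
    """One term of the compiled network (the machine-readable twin of one
    inflow/outflow pair in the ODE right-hand side).

    ``rate`` has any ``ind()`` indicators already resolved for this entry's
    context.  Proportional entries contribute flux ``rate × X[source]``;
    constant entries contribute ``rate`` into ``to`` only.
    """

    source: Optional[ProductState]  # None = EXTERNAL
    target: Optional[ProductState]  # None = SINK
    rate: RateExpr
    offspring: RateExpr
    flux_mode: str
    provenance: tuple[str, ...]

    @property
    def from_name(self) -> str:
        return self.source.name if self.source is not None else EXTERNAL

    @property
    def to_name(self) -> str:
        return self.target.name if self.target is not None else SINK


@dataclass
class CompiledNetwork:
    """Flattened product state space plus the flux table."""

    chart_name: str
    product_states: tuple[ProductState, ...]
    fluxes: tuple[FluxEntry, ...]
    parameters: dict[str, float]
    region_names: tuple[str, ...]
    #: authored state name -> indices of product states occupying it
    state_groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {p.name: i for i, p in enumerate(self.product_states)}

    @property
    def n_states(self) -> int:
        return len(self.product_states)

    def state_names(self) -> list[str]:
        return [p.name for p in self.product_states]

    def occupancy_lookup(self, x: Sequence[float]):
        """Return ``pop()`` semantics over a product-state vector: the
        occupancy of an authored state is the sum over product states whose
        coordinate lies in it."""
        groups = self.state_groups

        def lookup(state: str) -> float:
            idxs = groups[state]  # KeyError -> EvalError upstream
            return float(sum(x[i] for i in idxs))

        return lookup


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------


def _entry_leaf(chart: Statechart, name: str) -> str:
    """Descend through initial substates until a leaf is reached."""
    s = chart.find_state(name)
    if s is None:
        raise ChartError(f"unknown state {name!r}")
    while s.is_compound:
        s = next(c for c in s.substates if c.name == s.initial_substate)
    return s.name


def _override_for(src: State, leaf: str, mapping: Mapping[str, RateExpr]) -> Optional[RateExpr]:
    """Rate override for a leaf of a compound source: the innermost mapping
    key on the path from the leaf up to (not including) the compound."""
    path: list[str] = []

    def descend(s: State, trail: list[str]) -> bool:
        if s.name == leaf:
            path.extend(trail + [s.name])
            return True
        return any(descend(c, trail + [s.name]) for c in s.substates)

    descend(src, [])
    for name in reversed(path[1:]):  # innermost first, excluding src itself
        if name in mapping:
            return mapping[name]
    return None


def flatten(chart: Statechart) -> list[FlatRegion]:
    """Remove hierarchy: per-region leaf automata with overrides and entry
    redirection applied; guards and labels preserved on every generated
    transition."""
    require_valid(chart)
    out: list[FlatRegion] = []
    for region in chart.regions:
        leaves = tuple(s.name for s in region.leaf_states())
        flat: list[FlatTransition] = []
        for t in region.transitions:
            if t.target == SINK:
                target = SINK
            else:
                target = _entry_leaf(chart, t.target)
            if t.source == ORIGIN:
                sources = [(ORIGIN, t.rate if isinstance(t.rate, RateExpr) else None)]
            else:
                src_state = chart.find_state(t.source)
                assert src_state is not None
                if isinstance(t.rate, Mapping):
                    srcs = []
                    for leaf_state in src_state.leaves():
                        ov = _override_for(src_state, leaf_state.name, t.rate)
                        if ov is None:
                            raise ChartError(
                                f"per-substate rate on {t.describe()} gives no rate for"
                                f" substate {leaf_state.name!r}"
                            )
                        srcs.append((leaf_state.name, ov))
                    sources = srcs
                else:
                    sources = [(ls.name, t.rate) for ls in src_state.leaves()]
            for src_leaf, rate in sources:
                flat.append(
                    FlatTransition(
                        source=src_leaf,
                        target=target,
                        rate=rate,
                        guard=t.guard,
                        label=t.label,
                        offspring=t.offspring,
                        flux_mode=t.flux_mode,
                        provenance=f"{region.name}:{t.describe()}"
                        + (f"@{src_leaf}" if src_leaf != t.source else ""),
                    )
                )
        out.append(
            FlatRegion(
                name=region.name,
                leaves=leaves,
                transitions=tuple(flat),
                initial_leaf=chart.initial_leaf(region),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


def count_product_states(chart: Statechart) -> int:
    """Product of per-region leaf-state counts."""
    require_valid(chart)
    n = 1
    for r in chart.regions:
        n *= len(r.leaf_states())
    return n


def _coords_test_factory(chart: Statechart, region_names: Sequence[str]):
    """Build, once per chart, a maker of coordinate predicates.

    The predicate answers "is the active coordinate of S's region S or a
    descendant of S?" — descendant semantics make ``in(C)`` for compound C
    true whenever the coordinate is any leaf inside C.
    """
    pos = {name: i for i, name in enumerate(region_names)}
    leaf_sets: dict[str, set[str]] = {}
    region_index: dict[str, int] = {}
    for r in chart.regions:
        for s in r.walk_states():
            region_index[s.name] = pos[r.name]
            leaf_sets[s.name] = {x.name for x in s.leaves()}

    def make(coords: Sequence[str]):
        def test(state: str) -> bool:
            ri = region_index.get(state)
            if ri is None:
                raise ChartError(f"predicate references unknown state {state!r}")
            return coords[ri] in leaf_sets[state]

        return test

    return make


def _resolve_couplings(
    flat_regions: Sequence[FlatRegion],
) -> dict[str, dict[str, list[FlatTransition]]]:
    """Group labelled flat transitions as label → region → members.

    Each label must span at least two regions and carry exactly one
    rate-bearing authored member; several members in the *same* region are
    alternative branches, selected by which member's source coordinate is
    active.
    """
    groups: dict[str, dict[str, list[FlatTransition]]] = {}
    for fr in flat_regions:
        for t in fr.transitions:
            if t.label is not None:
                groups.setdefault(t.label, {}).setdefault(fr.name, []).append(t)
    for label, per_region in list(groups.items()):
        if sum(len(v) for v in per_region.values()) == 1:
            del groups[label]  # degenerate single-member label: ordinary move
            continue
        if len(per_region) < 2:
            raise ChartError(
                f"coupling label {label!r} does not span at least two regions"
            )
        for rname, members in per_region.items():
            seen: set[str] = set()
            for m in members:
                if m.source in seen:
                    raise ChartError(
                        f"label {label!r}: two members of region {rname!r} share"
                        f" source {m.source!r} (ambiguous synchronization)"
                    )
                seen.add(m.source)
    return groups


def expand(chart: Statechart) -> CompiledNetwork:
    """Expand a valid chart into its product state space and flux table."""
    flat_regions = flatten(chart)
    region_names = tuple(fr.name for fr in flat_regions)
    n = 1
    for fr in flat_regions:
        n *= len(fr.leaves)
    if n > MAX_PRODUCT_STATES:
        raise ChartError(
            f"product state space has {n} states, above the cap of {MAX_PRODUCT_STATES}"
        )

    product_states = tuple(
        ProductState(coords)
        for coords in itertools.product(*(fr.leaves for fr in flat_regions))
    )
    coupling_groups = _resolve_couplings(flat_regions)
    make_test = _coords_test_factory(chart, region_names)

    fluxes: list[FluxEntry] = []

    # --- single-region (uncoupled) moves ---------------------------------
    for ri, fr in enumerate(flat_regions):
        for t in fr.transitions:
            if t.label is not None and len(coupling_groups.get(t.label, {})) >= 2:
                continue  # handled as a joint move below
            if t.source == ORIGIN:
                continue  # handled with influxes below
            for ps in product_states:
                if ps.coords[ri] != t.source:
                    continue
                test = make_test(ps.coords)
                if not t.guard.evaluate(test):
                    continue
                if t.target == SINK:
                    target = None
                else:
                    target = ProductState(
                        ps.coords[:ri] + (t.target,) + ps.coords[ri + 1 :]
                    )
                assert t.rate is not None
                fluxes.append(
                    FluxEntry(
                        source=ps,
                        target=target,
                        rate=t.rate.bind_coords(test),
                        offspring=t.offspring,
                        flux_mode=t.flux_mode,
                        provenance=(t.provenance,),
                    )
                )

    # --- coupled (labelled) joint moves -----------------------------------
    region_pos = {name: i for i, name in enumerate(region_names)}
    for label, per_region in coupling_groups.items():
        for ps in product_states:
            chosen: list[tuple[int, FlatTransition]] = []
            enabled = True
            for rname, members in per_region.items():
                ri = region_pos[rname]
                member = next((m for m in members if m.source == ps.coords[ri]), None)
                if member is None:
                    # a synchronized partner has no enabled move here: the
                    # whole joint transition is disabled (no half-firing)
                    enabled = False
                    break
                chosen.append((ri, member))
            if not enabled:
                continue
            test = make_test(ps.coords)
            if not all(m.guard.evaluate(test) for _, m in chosen):
                continue
            bearer = next(m for _, m in chosen if m.rate is not None)
            if any(m.target == SINK for _, m in chosen):
                target = None
            else:
                coords = list(ps.coords)
                for ri, m in chosen:
                    coords[ri] = m.target
                target = ProductState(tuple(coords))
            fluxes.append(
                FluxEntry(
                    source=ps,
                    target=target,
                    rate=bearer.rate.bind_coords(test),
                    offspring=bearer.offspring,
                    flux_mode=bearer.flux_mode,
                    provenance=tuple(m.provenance for _, m in chosen),
                )
            )

    # --- constant influxes -------------------------------------------------
    def influx_target(ri: int, target_leaf: str, context: Mapping[str, str]) -> ProductState:
        coords = []
        for rj, fr in enumerate(flat_regions):
            if rj == ri:
                coords.append(target_leaf)
            elif fr.name in context:
                coords.append(_entry_leaf(chart, context[fr.name]))
            else:
                coords.append(fr.initial_leaf)
        return ProductState(tuple(coords))

    for ri, fr in enumerate(flat_regions):
        for t in fr.transitions:
            if t.source != ORIGIN:
                continue
            assert t.rate is not None and t.target != SINK
            fluxes.append(
                FluxEntry(
                    source=None,
                    target=influx_target(ri, t.target, {}),
                    rate=t.rate,
                    offspring=t.offspring,
                    flux_mode="constant",
                    provenance=(t.provenance,),
                )
            )
    for inf in chart.influxes:
        region = chart.region_of(inf.target)
        assert region is not None
        ri = region_names.index(region.name)
        fluxes.append(
            FluxEntry(
                source=None,
                target=influx_target(ri, _entry_leaf(chart, inf.target), inf.context),
                rate=inf.rate,
                offspring=parse_rate(1.0),
                flux_mode="constant",
                provenance=(f"influx->{inf.target}",),
            )
        )

    # --- pop() groups ------------------------------------------------------
    state_groups: dict[str, tuple[int, ...]] = {}
    index = {p.coords: i for i, p in enumerate(product_states)}
    for r in chart.regions:
        ri = region_names.index(r.name)
        for s in r.walk_states():
            leaves = {x.name for x in s.leaves()}
            state_groups[s.name] = tuple(
                i for p, i in index.items() if p[ri] in leaves
            )

    return CompiledNetwork(
        chart_name=chart.name,
        product_states=product_states,
        fluxes=tuple(fluxes),
        parameters=dict(chart.parameters),
        region_names=region_names,
        state_groups=state_groups,
    )
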