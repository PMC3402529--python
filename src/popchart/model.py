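"""Statechart data model and structural validation.

A :class:`Statechart` is a set of parallel *regions* (tracks), each a small
state machine over simple and compound states.  A population individual
occupies one leaf state per region at any time; the compiler expands the
chart into the Cartesian product of the regions' leaves.

The chart stores continuous-time transition *intensities* only.  Whether the
model is read deterministically (ODE) or stochastically (event simulation)
is a runtime choice and has no representation here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union

from .expr import GuardExpr, RateExpr, TRUE_GUARD, parse_rate

__all__ = [
    "ORIGIN",
    "SINK",
    "State",
    "Transition",
    "Influx",
    "Region",
    "Statechart",
    "Diagnostic",
    "ChartError",
    "validate_chart",
    "FORMAT_VERSION",
]

#: Pseudostate names for constant influx sources and removal targets.
ORIGIN = "ORIGIN"
SINK = "SINK"

FORMAT_VERSION = 1

RateSpec = Union[RateExpr, Mapping[str, RateExpr], None]


class ChartError(ValueError):
    """Raised when a structurally invalid chart is used where validity is required."""


@dataclass
class State:
    """A simple state, or a compound state holding substates.

    Compound nesting may be arbitrarily deep.  A transition entering a
    compound state is redirected to ``initial_substate`` (recursively) at
    flattening time; a transition leaving one is factorized over all leaf
    substates.
    """

    name: str
    substates: tuple["State", ...] = ()
    initial_substate: Optional[str] = None

    @property
    def is_compound(self) -> bool:
        return bool(self.substates)

    def walk(self) -> Iterator["State"]:
        yield self
        for s in self.substates:
            yield from s.walk()

    def leaves(self) -> list["State"]:
        if not self.is_compound:
            return [self]
        out: list[State] = []
        for s in self.substates:
            out.extend(s.leaves())
        return out


@dataclass
class Transition:
    """A directed transition within one region.

    ``rate`` may be a single expression, or a mapping substate-name →
    expression when the source is compound and the per-substate rates differ
    (the "one arrow, several rates" factorization).  A ``None`` rate is legal
    only on a coupled transition that defers to its label's rate-bearing
    member.

    ``offspring`` is the number of individuals deposited at the target per
    departing individual: 2 encodes cell division into the next compartment,
    an expression like ``2*delta`` encodes division whose daughters are lost
    under treatment (δ=0).  ``flux_mode='constant'`` makes the flux
    independent of the source occupancy (forced when source is ORIGIN).
    """

    source: str
    target: str
    rate: RateSpec = None
    guard: GuardExpr = TRUE_GUARD
    label: Optional[str] = None
    offspring: RateExpr = field(default_factory=lambda: parse_rate(1.0))
    flux_mode: str = "proportional"  # or "constant"

    def rate_exprs(self) -> list[RateExpr]:
        if self.rate is None:
            return []
        if isinstance(self.rate, RateExpr):
            return [self.rate]
        return list(self.rate.values())

    def describe(self) -> str:
        lbl = f" [{self.label}]" if self.label else ""
        return f"{self.source}->{self.target}{lbl}"


@dataclass
class Influx:
    """Constant-rate external source depositing individuals into ``target``.

    ``context`` optionally pins the coordinates of other regions for the
    receiving product state; unspecified regions default to their initial
    leaves.
    """

    target: str
    rate: RateExpr
    context: Mapping[str, str] = field(default_factory=dict)


@dataclass
class Region:
    """One parallel track: a connected description of one aspect of the object."""

    name: str
    states: tuple[State, ...]
    transitions: tuple[Transition, ...] = ()
    initial: Optional[str] = None

    def walk_states(self) -> Iterator[State]:
        for s in self.states:
            yield from s.walk()

    def leaf_states(self) -> list[State]:
        out: list[State] = []
        for s in self.states:
            out.extend(s.leaves())
        return out


@dataclass
class Statechart:
    name: str
    regions: tuple[Region, ...]
    parameters: dict[str, float] = field(default_factory=dict)
    influxes: tuple[Influx, ...] = ()
    version: int = FORMAT_VERSION

    # -- lookup helpers ----------------------------------------------------

    def state_map(self) -> dict[str, State]:
        out: dict[str, State] = {}
        for r in self.regions:
            for s in r.walk_states():
                out[s.name] = s
        return out

    def region_of(self, state_name: str) -> Optional[Region]:
        for r in self.regions:
            for s in r.walk_states():
                if s.name == state_name:
                    return r
        return None

    def find_state(self, name: str) -> Optional[State]:
        return self.state_map().get(name)

    def leaf_descendants(self, state_name: str) -> list[str]:
        """Leaf states of ``state_name`` (itself, if simple)."""
        s = self.find_state(state_name)
        if s is None:
            raise ChartError(f"unknown state {state_name!r}")
        return [x.name for x in s.leaves()]

    def initial_leaf(self, region: Region) -> str:
        """The region's entry leaf: its initial state, descended through
        initial substates until a leaf is reached."""
        if region.initial is None:
            raise ChartError(f"region {region.name!r} has no initial state")
        s = next((x for x in region.walk_states() if x.name == region.initial), None)
        if s is None:
            raise ChartError(f"region {region.name!r} initial {region.initial!r} not found")
        while s.is_compound:
            s = next(x for x in s.substates if x.name == s.initial_substate)
        return s.name


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    code: str
    message: str
    location: str = ""

    def __str__(self) -> str:
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.code}: {self.message}{loc}"


def validate_chart(chart: Statechart) -> list[Diagnostic]:
    """Return every structural violation in the chart (empty list = valid).

    Checks cover: name uniqueness, transition endpoints, declared
    parameters, compound-state wiring, guard placement (guards may only
    reference *other* regions), and coupling labels (exactly one
    rate-bearing member, members spanning at least two regions).
    """
    diags: list[Diagnostic] = []

    # region name uniqueness
    seen_regions: set[str] = set()
    for r in chart.regions:
        if r.name in seen_regions:
            diags.append(Diagnostic("duplicate-region", f"region name {r.name!r} is reused"))
        seen_regions.add(r.name)

    # chart-wide state name uniqueness + per-state structure
    state_owner: dict[str, str] = {}
    for r in chart.regions:
        for s in r.walk_states():
            if s.name in state_owner:
                diags.append(
                    Diagnostic("duplicate-state", f"state name {s.name!r} is reused", s.name)
                )
            state_owner[s.name] = r.name
            if s.is_compound:
                if s.initial_substate is None:
                    diags.append(
                        Diagnostic(
                            "missing-initial-substate",
                            f"compound state {s.name!r} lacks an initial substate",
                            s.name,
                        )
                    )
                elif s.initial_substate not in {c.name for c in s.substates}:
                    diags.append(
                        Diagnostic(
                            "bad-initial-substate",
                            f"compound {s.name!r}: initial substate {s.initial_substate!r}"
                            " is not a direct substate",
                            s.name,
                        )
                    )
            elif s.initial_substate is not None:
                diags.append(
                    Diagnostic(
                        "initial-on-simple",
                        f"simple state {s.name!r} carries an initial substate",
                        s.name,
                    )
                )

    # region initial states
    for r in chart.regions:
        if r.initial is None:
            diags.append(
                Diagnostic("missing-initial", f"region {r.name!r} declares no initial state", r.name)
            )
        elif all(s.name != r.initial for s in r.walk_states()):
            diags.append(
                Diagnostic(
                    "bad-initial",
                    f"region {r.name!r}: initial {r.initial!r} names no state in the region",
                    r.name,
                )
            )

    def check_symbols(expr: RateExpr, where: str) -> None:
        for p in expr.param_refs():
            if p not in chart.parameters:
                diags.append(
                    Diagnostic("undeclared-parameter", f"parameter {p!r} is not declared", where)
                )
        for s in expr.pop_refs() | expr.ind_refs():
            if s not in state_owner:
                diags.append(
                    Diagnostic("unknown-state-ref", f"expression references unknown state {s!r}", where)
                )

    # transitions
    labels: dict[str, list[tuple[Region, Transition]]] = {}
    for r in chart.regions:
        region_states = {s.name for s in r.walk_states()}
        for t in r.transitions:
            where = f"{r.name}:{t.describe()}"
            if t.source != ORIGIN and t.source not in region_states:
                diags.append(
                    Diagnostic(
                        "unknown-endpoint",
                        f"transition source {t.source!r} names no state in region {r.name!r}",
                        where,
                    )
                )
            if t.target != SINK and t.target not in region_states:
                diags.append(
                    Diagnostic(
                        "unknown-endpoint",
                        f"transition target {t.target!r} names no state in region {r.name!r}",
                        where,
                    )
                )
            if t.source == ORIGIN and t.flux_mode != "constant":
                diags.append(
                    Diagnostic(
                        "origin-not-constant",
                        "ORIGIN-sourced transitions must have flux_mode 'constant'",
                        where,
                    )
                )
            if t.flux_mode not in ("proportional", "constant"):
                diags.append(
                    Diagnostic("bad-flux-mode", f"unknown flux_mode {t.flux_mode!r}", where)
                )
            if t.rate is None and t.label is None:
                diags.append(
                    Diagnostic("missing-rate", "unlabeled transition carries no rate", where)
                )
            if isinstance(t.rate, Mapping):
                src = chart.find_state(t.source) if t.source != ORIGIN else None
                if src is None or not src.is_compound:
                    diags.append(
                        Diagnostic(
                            "per-substate-on-simple",
                            "per-substate rates are legal only on a compound source",
                            where,
                        )
                    )
                else:
                    members = {x.name for x in src.walk()} - {src.name}
                    for key in t.rate:
                        if key not in members:
                            diags.append(
                                Diagnostic(
                                    "bad-substate-key",
                                    f"per-substate rate names {key!r}, not a substate of {t.source!r}",
                                    where,
                                )
                            )
            for expr in t.rate_exprs():
                check_symbols(expr, where)
            check_symbols(t.offspring, where)
            for sname in t.guard.state_refs():
                owner = state_owner.get(sname)
                if owner is None:
                    diags.append(
                        Diagnostic("unknown-state-ref", f"guard references unknown state {sname!r}", where)
                    )
                elif owner == r.name:
                    diags.append(
                        Diagnostic(
                            "guard-own-region",
                            f"guard references {sname!r} in the transition's own region",
                            where,
                        )
                    )
            for sname in set().union(*(e.ind_refs() for e in t.rate_exprs()), set()):
                if state_owner.get(sname) == r.name:
                    diags.append(
                        Diagnostic(
                            "ind-own-region",
                            f"ind({sname}) references the transition's own region"
                            " (use a per-substate rate instead)",
                            where,
                        )
                    )
            if t.label is not None:
                labels.setdefault(t.label, []).append((r, t))

    # coupling labels
    for label, members in labels.items():
        bearers = [t for _, t in members if t.rate is not None]
        if len(bearers) != 1:
            diags.append(
                Diagnostic(
                    "coupling-rate-conflict",
                    f"label {label!r} must have exactly one rate-bearing member, found {len(bearers)}",
                    label,
                )
            )
        if len(members) > 1 and len({r.name for r, _ in members}) < 2:
            diags.append(
                Diagnostic(
                    "coupling-single-region",
                    f"label {label!r} couples transitions within a single region only",
                    label,
                )
            )

    # influxes
    for inf in chart.influxes:
        if inf.target not in state_owner:
            diags.append(
                Diagnostic("unknown-endpoint", f"influx targets unknown state {inf.target!r}", inf.target)
            )
        check_symbols(inf.rate, f"influx->{inf.target}")
        for rname, sname in inf.context.items():
            if rname not in seen_regions:
                diags.append(
                    Diagnostic("unknown-region", f"influx context names unknown region {rname!r}")
                )
            elif state_owner.get(sname) != rname:
                diags.append(
                    Diagnostic(
                        "bad-influx-context",
                        f"influx context {rname}={sname!r} names no state of that region",
                    )
                )

    return diags


def require_valid(chart: Statechart) -> None:
    diags = validate_chart(chart)
    if diags:
        raise ChartError(
            f"chart {chart.name!r} is invalid: " + "; ".join(str(d) for d in diags[:5])
        )
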