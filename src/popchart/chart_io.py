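"""Reading and writing the declarative chart document format, plus DOT export.

A chart document is YAML with exactly these top-level keys::

    name: infection
    version: 1
    parameters: {p: 0.01}
    regions:
      - name: cell
        initial: Uninfected
        states:
          - Uninfected
          - Infected
          - name: Dividing          # a compound state
            initial: G1
            states: [G1, SG2M]
        transitions:
          - {from: Uninfected, to: Infected, rate: "p * pop(Virus)"}
    influxes:
      - {target: Uninfected, rate: "sigma"}

Transitions accept ``from``/``to`` (``ORIGIN``/``SINK`` allowed), ``rate``
(string, number, or a substate→rate mapping), ``guard``, ``label``,
``offspring`` and ``mode`` (proportional/constant).  Unknown keys anywhere
are hard errors: a typo in a rate key must never silently drop a term from
the model.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .expr import RateExpr, parse_guard, parse_rate
from .model import (
    FORMAT_VERSION,
    ORIGIN,
    SINK,
    ChartError,
    Influx,
    Region,
    State,
    Statechart,
    Transition,
    require_valid,
    validate_chart,
)

__all__ = ["parse_chart", "parse_chart_file", "write_chart", "write_chart_file", "export_dot"]

_TOP_KEYS = {"name", "version", "parameters", "regions", "influxes"}
_REGION_KEYS = {"name", "initial", "states", "transitions"}
_STATE_KEYS = {"name", "initial", "states"}
_TRANSITION_KEYS = {"from", "to", "rate", "guard", "label", "offspring", "mode"}
_INFLUX_KEYS = {"target", "rate", "context"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], what: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ChartError(f"unknown key(s) {sorted(unknown)} in {what}")


def _parse_state(node: Any) -> State:
    if isinstance(node, str):
        return State(node)
    if not isinstance(node, Mapping):
        raise ChartError(f"state entry must be a name or mapping, got {node!r}")
    _check_keys(node, _STATE_KEYS, f"state {node.get('name')!r}")
    name = node.get("name")
    if not isinstance(name, str):
        raise ChartError("compound state entry lacks a 'name'")
    subs = tuple(_parse_state(s) for s in node.get("states", []))
    if subs and "initial" not in node:
        raise ChartError(f"compound state {name!r} lacks an 'initial' substate")
    return State(name, subs, node.get("initial"))


def _parse_rate_field(node: Any):
    if node is None:
        return None
    if isinstance(node, Mapping):
        return {str(k): parse_rate(v) for k, v in node.items()}
    return parse_rate(node)


def _parse_transition(node: Any, where: str) -> Transition:
    if not isinstance(node, Mapping):
        raise ChartError(f"transition in {where} must be a mapping, got {node!r}")
    _check_keys(node, _TRANSITION_KEYS, f"transition in {where}")
    for req in ("from", "to"):
        if req not in node:
            raise ChartError(f"transition in {where} lacks {req!r}")
    off = node.get("offspring", 1)
    return Transition(
        source=str(node["from"]),
        target=str(node["to"]),
        rate=_parse_rate_field(node.get("rate")),
        guard=parse_guard(node.get("guard")),
        label=node.get("label"),
        offspring=parse_rate(off),
        flux_mode=node.get("mode", "constant" if node["from"] == ORIGIN else "proportional"),
    )


def parse_chart(text: str) -> Statechart:
    """Parse a chart document; raises on the first structural diagnostic."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ChartError(f"document syntax error: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ChartError("chart document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "chart document")
    if "name" not in doc:
        raise ChartError("chart document lacks a 'name'")
    version = doc.get("version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise ChartError(f"unsupported format version {version!r}")

    params = {str(k): float(v) for k, v in (doc.get("parameters") or {}).items()}

    regions = []
    for rnode in doc.get("regions") or []:
        if not isinstance(rnode, Mapping):
            raise ChartError(f"region entry must be a mapping, got {rnode!r}")
        _check_keys(rnode, _REGION_KEYS, f"region {rnode.get('name')!r}")
        rname = rnode.get("name")
        if not isinstance(rname, str):
            raise ChartError("region lacks a 'name'")
        if "initial" not in rnode:
            raise ChartError(f"region {rname!r} lacks an 'initial' state")
        states = tuple(_parse_state(s) for s in rnode.get("states") or [])
        transitions = tuple(
            _parse_transition(t, f"region {rname!r}") for t in rnode.get("transitions") or []
        )
        regions.append(Region(rname, states, transitions, rnode["initial"]))

    influxes = []
    for inode in doc.get("influxes") or []:
        if not isinstance(inode, Mapping):
            raise ChartError(f"influx entry must be a mapping, got {inode!r}")
        _check_keys(inode, _INFLUX_KEYS, "influx")
        if "target" not in inode or "rate" not in inode:
            raise ChartError("influx lacks 'target' or 'rate'")
        influxes.append(
            Influx(str(inode["target"]), parse_rate(inode["rate"]), dict(inode.get("context") or {}))
        )

    chart = Statechart(str(doc["name"]), tuple(regions), params, tuple(influxes), version)
    diags = validate_chart(chart)
    if diags:
        raise ChartError(f"invalid chart {chart.name!r}: {diags[0]}")
    return chart


def parse_chart_file(path: str | Path) -> Statechart:
    return parse_chart(Path(path).read_text())


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _state_doc(s: State) -> Any:
    if not s.is_compound:
        return s.name
    return {
        "name": s.name,
        "initial": s.initial_substate,
        "states": [_state_doc(c) for c in s.substates],
    }


def _rate_doc(rate) -> Any:
    if rate is None:
        return None
    if isinstance(rate, RateExpr):
        return rate.source
    return {k: v.source for k, v in rate.items()}


def _transition_doc(t: Transition) -> dict:
    doc: dict[str, Any] = {"from": t.source, "to": t.target}
    r = _rate_doc(t.rate)
    if r is not None:
        doc["rate"] = r
    if not t.guard.is_true():
        doc["guard"] = str(t.guard)
    if t.label is not None:
        doc["label"] = t.label
    if t.offspring.source != "1.0":
        doc["offspring"] = t.offspring.source
    default_mode = "constant" if t.source == ORIGIN else "proportional"
    if t.flux_mode != default_mode:
        doc["mode"] = t.flux_mode
    return doc


def write_chart(chart: Statechart) -> str:
    """Emit the canonical document; ``parse_chart(write_chart(c))`` is
    structurally identical to ``c``."""
    doc: dict[str, Any] = {
        "name": chart.name,
        "version": chart.version,
        "parameters": dict(chart.parameters),
        "regions": [
            {
                "name": r.name,
                "initial": r.initial,
                "states": [_state_doc(s) for s in r.states],
                "transitions": [_transition_doc(t) for t in r.transitions],
            }
            for r in chart.regions
        ],
    }
    if chart.influxes:
        doc["influxes"] = [
            {"target": i.target, "rate": i.rate.source, **({"context": dict(i.context)} if i.context else {})}
            for i in chart.influxes
        ]
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def write_chart_file(chart: Statechart, path: str | Path) -> None:
    Path(path).write_text(write_chart(chart))


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def _dot_escape(name: str) -> str:
    return '"%s"' % name.replace('"', '\\"')


def export_dot(chart: Statechart, level: str = "authored") -> str:
    """Render the chart as a Graphviz digraph.

    ``authored`` shows the diagram as drawn — compound states as clusters,
    one edge per authored transition.  ``expanded`` runs the compiler first
    and shows the product graph: one node per product state, one edge per
    flux entry (the view that makes coupling and guard pruning visible).
    """
    if level == "expanded":
        from .expansion import expand

        net = expand(chart)
        lines = [f"digraph {_dot_escape(chart.name)} {{", "  rankdir=LR;"]
        for p in net.product_states:
            lines.append(f"  {_dot_escape(p.name)};")
        for e in net.fluxes:
            attrs = f'label="{e.rate.source}"'
            lines.append(f"  {_dot_escape(e.from_name)} -> {_dot_escape(e.to_name)} [{attrs}];")
        lines.append("}")
        return "\n".join(lines) + "\n"

    if level != "authored":
        raise ValueError(f"unknown level {level!r}")

    lines = [f"digraph {_dot_escape(chart.name)} {{", "  rankdir=LR;", "  compound=true;"]
    cluster_id = [0]

    def emit_state(s: State, indent: str) -> None:
        if not s.is_compound:
            lines.append(f"{indent}{_dot_escape(s.name)};")
            return
        cluster_id[0] += 1
        lines.append(f"{indent}subgraph cluster_{cluster_id[0]} {{")
        lines.append(f'{indent}  label="{s.name}";')
        for c in s.substates:
            emit_state(c, indent + "  ")
        lines.append(f"{indent}}}")

    needed_pseudo = set()
    for ri, r in enumerate(chart.regions):
        cluster_id[0] += 1
        lines.append(f"  subgraph cluster_{cluster_id[0]} {{")
        lines.append(f'    label="region {r.name}";')
        for s in r.states:
            emit_state(s, "    ")
        lines.append("  }")
        for t in r.transitions:
            needed_pseudo.update({t.source, t.target} & {ORIGIN, SINK})
    for inf in chart.influxes:
        needed_pseudo.add(ORIGIN)
    for p in needed_pseudo:
        shape = "point" if p == ORIGIN else "doublecircle"
        lines.append(f"  {_dot_escape(p)} [shape={shape}];")
    for r in chart.regions:
        for t in r.transitions:
            label_bits = []
            if t.rate is not None:
                label_bits.append(_rate_doc(t.rate) if isinstance(t.rate, RateExpr) else "per-substate")
            if not t.guard.is_true():
                label_bits.append(f"[{t.guard}]")
            if t.label:
                label_bits.append(f"{{{t.label}}}")
            attrs = f'label="{" ".join(str(b) for b in label_bits)}"'
            lines.append(f"  {_dot_escape(t.source)} -> {_dot_escape(t.target)} [{attrs}];")
    for inf in chart.influxes:
        lines.append(f'  {_dot_escape(ORIGIN)} -> {_dot_escape(inf.target)} [label="{inf.rate.source}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
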