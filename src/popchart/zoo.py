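"""Programmatic builders for the worked example charts.

These are both the package's fixture generators and a user's starting
library: each builder returns a valid :class:`Statechart` that can be
written to disk, compiled and simulated.  The examples cover the semantic
ladder one rung at a time — elementary transitions, branching, compound
states, independent parallel tracks, weak and strong cross-track
dependencies, label-coupled transitions — plus the staged thymocyte
"conveyor belt" builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .expr import parse_guard, parse_rate
from .model import (
    ORIGIN,
    SINK,
    Influx,
    Region,
    State,
    Statechart,
    Transition,
    require_valid,
)

__all__ = ["EXAMPLE_NAMES", "build_example", "ConveyorConfig", "build_conveyor_belt"]


def _t(src, dst, rate=None, guard=None, label=None, offspring=1, mode=None):
    return Transition(
        source=src,
        target=dst,
        rate={k: parse_rate(v) for k, v in rate.items()} if isinstance(rate, Mapping)
        else (parse_rate(rate) if rate is not None else None),
        guard=parse_guard(guard),
        label=label,
        offspring=parse_rate(offspring),
        flux_mode=mode or ("constant" if src == ORIGIN else "proportional"),
    )


def _chart(name, regions, params, influxes=()):
    chart = Statechart(name, tuple(regions), dict(params), tuple(influxes))
    require_valid(chart)
    return chart


# ---------------------------------------------------------------------------
# Elementary examples
# ---------------------------------------------------------------------------


def _infection(p):
    """Mass-action viral infection: uninfected cells become infected at a
    rate proportional to the virus population (rate ``p·pop(Virus)``)."""
    region = Region(
        "cell",
        (State("Uninfected"), State("Infected"), State("Virus")),
        (_t("Uninfected", "Infected", "p * pop(Virus)"),),
        initial="Uninfected",
    )
    return _chart("infection", [region], {"p": 0.01, **p})


def _gene_switch(p):
    """Inactive ⇄ active gene toggling."""
    region = Region(
        "gene",
        (State("Inactive"), State("Active")),
        (_t("Inactive", "Active", "p_on"), _t("Active", "Inactive", "p_off")),
        initial="Inactive",
    )
    return _chart("gene_switch", [region], {"p_on": 0.3, "p_off": 0.1, **p})


def _dn_dp_sp(p):
    """Linear thymocyte differentiation chain DN → DP → SP."""
    region = Region(
        "differentiation",
        (State("DN"), State("DP"), State("SP")),
        (_t("DN", "DP", "p1"), _t("DP", "SP", "p2")),
        initial="DN",
    )
    return _chart("dn_dp_sp", [region], {"p1": 0.5, "p2": 0.25, **p})


def _branching(p):
    """Conditional differentiation: DP branches to SP4 or SP8."""
    region = Region(
        "differentiation",
        (State("DP"), State("SP4"), State("SP8")),
        (_t("DP", "SP4", "p1"), _t("DP", "SP8", "p2")),
        initial="DP",
    )
    return _chart("branching", [region], {"p1": 0.3, "p2": 0.2, **p})


def _compound_demo(p):
    """A three-substate compound with internal progression, a factored exit
    to SINK carrying per-substate death rates, and an origin influx with
    in-place proliferation (the full elementary vocabulary in one chart)."""
    compound = State("A", (State("A1"), State("A2"), State("A3")), "A1")
    region = Region(
        "stage",
        (compound, State("B")),
        (
            _t("A1", "A2", "k12"),
            _t("A2", "A3", "k23"),
            _t("A", SINK, {"A1": "d1", "A2": "d2", "A3": "d3"}),
            _t("A", "B", "m"),
            _t("B", "B", "a", offspring=2),
            _t("B", SINK, "mu"),
        ),
        initial="A",
    )
    params = {"k12": 0.4, "k23": 0.4, "d1": 0.05, "d2": 0.03, "d3": 0.01,
              "m": 0.2, "a": 0.1, "mu": 0.05, "sigma": 1.0}
    return _chart("compound_demo", [region], {**params, **p},
                  influxes=(Influx("A", parse_rate("sigma")),))


# ---------------------------------------------------------------------------
# Parallel-track examples
# ---------------------------------------------------------------------------


def _two_track(name, guard=None, weak=False, extra_params=()):
    upper = Region("upper", (State("A"), State("B")),
                   (_t("A", "B", "k1", guard=guard),), initial="A")
    lower_rate = "kx_a * ind(A) + kx_b * ind(B)" if weak else "k2"
    lower = Region("lower", (State("X"), State("Y")),
                   (_t("X", "Y", lower_rate),), initial="X")
    params = {"k1": 0.2}
    params.update({"kx_a": 0.3, "kx_b": 0.05} if weak else {"k2": 0.3})
    params.update(extra_params)
    return _chart(name, [upper, lower], params)


def _parallel_independent(p):
    """Two fully independent tracks: 2×2 product states, 4 flux entries."""
    c = _two_track("parallel_independent")
    c.parameters.update(p)
    return c


def _parallel_weak(p):
    """Weak dependency: the lower track's rate depends on the upper track's
    coordinate (``ind(A)``/``ind(B)`` indicators select the context rate)."""
    c = _two_track("parallel_weak", weak=True)
    c.parameters.update(p)
    return c


def _parallel_strong(p):
    """Strong dependency: A→B is impossible while the lower track is in Y
    (guard ``not in(Y)`` prunes the (A,Y)→(B,Y) entry)."""
    c = _two_track("parallel_strong", guard="not in(Y)")
    c.parameters.update(p)
    return c


def _lymphocyte(p):
    """Lymphocytes differentiating, migrating and dividing in parallel.

    Differentiation track Naive→Effector→Memory (re-activation
    Memory→Effector), migration track LymphNode ⇄ PeripheralTissue, and a
    cell-cycle track G0 → compound ``cycle`` {G1, SG2M} → back to G0 with
    offspring 2 (clonal duplication).  While a cell is inside ``cycle`` all
    differentiation and migration transitions are blocked — the strong
    dependency ``not in(cycle)``.  Activation rates use a saturating
    ligand-competition form: ``b·ligand/(K + pop(Naive) + pop(Memory))``,
    with the available ligand a parameter and the competing populations in
    the denominator.  3 × 2 × 3 leaves → 18 product states.
    """
    blocked = "not in(cycle)"
    f_naive = "b_n * ligand / (K + pop(Naive) + pop(Memory))"
    f_memory = "b_m * ligand / (K + pop(Naive) + pop(Memory))"
    differentiation = Region(
        "differentiation",
        (State("Naive"), State("Effector"), State("Memory")),
        (
            _t("Naive", "Effector", f_naive, guard=blocked),
            _t("Effector", "Memory", "m_em", guard=blocked),
            _t("Memory", "Effector", f_memory, guard=blocked),
            _t("Naive", SINK, "d_n", guard=blocked),
            _t("Effector", SINK, "d_e", guard=blocked),
            _t("Memory", SINK, "d_m", guard=blocked),
        ),
        initial="Naive",
    )
    migration = Region(
        "location",
        (State("LymphNode"), State("PeripheralTissue")),
        (
            _t("LymphNode", "PeripheralTissue", "m_out", guard=blocked),
            _t("PeripheralTissue", "LymphNode", "m_in", guard=blocked),
        ),
        initial="LymphNode",
    )
    cycling = Region(
        "cellcycle",
        (State("G0"), State("cycle", (State("G1"), State("SG2M")), "G1")),
        (
            _t("G0", "cycle", "k_enter"),
            _t("G1", "SG2M", "k_cycle"),
            _t("SG2M", "G0", "lam", offspring=2),
        ),
        initial="G0",
    )
    params = {
        "b_n": 0.5, "b_m": 1.0, "ligand": 100.0, "K": 50.0,
        "m_em": 0.2, "d_n": 0.02, "d_e": 0.1, "d_m": 0.01,
        "m_out": 0.3, "m_in": 0.3,
        "k_enter": 0.05, "k_cycle": 1.0, "lam": 1.0,
        "sigma": 1.0,
    }
    params.update(p)
    return _chart(
        "lymphocyte",
        [differentiation, migration, cycling],
        params,
        influxes=(Influx("Naive", parse_rate("sigma")),),
    )


def _coupled_division(p):
    """Division coupled to generation advance.

    The cycle track alternates G0 → S (entering division) and S → G0; the
    S → G0 exit divides the cell (offspring 2) and, through the shared label
    ``existing``, simultaneously advances the generation track T1 → T2 → T3.
    A cell at T3 has no further coupled partner, so the joint transition is
    disabled there — T3 cells no longer divide.
    """
    cycle = Region(
        "cycle",
        (State("G0"), State("S")),
        (
            _t("G0", "S", "k_enter"),
            _t("S", "G0", "lam", label="existing", offspring=2),
        ),
        initial="G0",
    )
    generation = Region(
        "generation",
        (State("T1"), State("T2"), State("T3")),
        (
            _t("T1", "T2", label="existing"),
            _t("T2", "T3", label="existing"),
        ),
        initial="T1",
    )
    return _chart("coupled_division", [cycle, generation],
                  {"k_enter": 0.4, "lam": 1.0, **p})


def _student(p):
    """Five academic years × sport membership × civic status: 20 combined
    states from three innocuous-looking parallel tracks."""
    years = Region(
        "year",
        tuple(State(f"Y{i}") for i in range(1, 6)),
        tuple(_t(f"Y{i}", f"Y{i+1}", "adv") for i in range(1, 5))
        + tuple(_t(f"Y{i}", SINK, "fail") for i in range(1, 6)),
        initial="Y1",
    )
    sport = Region(
        "sport",
        (State("NoSport"), State("Sport")),
        (_t("NoSport", "Sport", "join"), _t("Sport", "NoSport", "quit")),
        initial="NoSport",
    )
    civic = Region(
        "civic",
        (State("Single"), State("Married")),
        (_t("Single", "Married", "wed"),),
        initial="Single",
    )
    return _chart("student", [years, sport, civic],
                  {"adv": 1.0, "fail": 0.1, "join": 0.2, "quit": 0.1, "wed": 0.05, **p})


_BUILDERS = {
    "infection": _infection,
    "gene_switch": _gene_switch,
    "dn_dp_sp": _dn_dp_sp,
    "branching": _branching,
    "compound_demo": _compound_demo,
    "parallel_independent": _parallel_independent,
    "parallel_weak": _parallel_weak,
    "parallel_strong": _parallel_strong,
    "lymphocyte": _lymphocyte,
    "coupled_division": _coupled_division,
    "student": _student,
}

EXAMPLE_NAMES = tuple(_BUILDERS)


def build_example(name: str, params: Optional[Mapping[str, float]] = None) -> Statechart:
    """Build a named example chart, optionally overriding declared parameters."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown example {name!r}; choose from {', '.join(EXAMPLE_NAMES)}"
        ) from None
    overrides = dict(params or {})
    chart = builder({})
    unknown = set(overrides) - set(chart.parameters)
    if unknown:
        raise KeyError(f"override(s) {sorted(unknown)} are not parameters of {name!r}")
    return builder(overrides) if overrides else chart


# ---------------------------------------------------------------------------
# Conveyor belt builder
# ---------------------------------------------------------------------------


@dataclass
class ConveyorConfig:
    """Configuration of the staged thymocyte differentiation chart.

    Thymocytes enter as double-negative (DN) progenitors at constant rate
    ``sigma``, proliferate through numbered generations (two daughters per
    division, scaled by the treatment indicator ``delta``: 1 normally, 0
    while dividing cells are being depleted), differentiate DN→DP→SP4/SP8
    with per-generation rates ``m_i`` that by default increase with
    generation, die naturally at stage-specific rates, and finally egress to
    the periphery at rates ``e4``/``e8``.  Generation counts and rate values
    are fully configurable; the defaults are documentation-scale examples.
    """

    n_dn: int = 4
    n_dp: int = 4
    n_sp: int = 1
    sigma: float = 10.0
    delta: float = 1.0
    #: per-generation proliferation rates; scalar = same for every generation
    a_dn: float | Sequence[float] = 0.8
    a_dp: float | Sequence[float] = 0.6
    #: per-generation differentiation rates (non-decreasing by default)
    m_dn: Optional[Sequence[float]] = None
    m_dp: Optional[Sequence[float]] = None
    #: natural death rates per stage
    d_dn: float = 0.05
    d_dp: float = 0.05
    d_sp: float = 0.05
    #: selection death acting on DP cells (positive/negative selection)
    s_dp: float = 0.1
    #: egress to the periphery
    e4: float = 0.5
    e8: float = 0.5
    #: fraction of differentiating DP cells becoming CD4 (rest become CD8)
    frac_cd4: float = 0.6
    #: egress from the last SP generation only, or from all of them
    egress_from: str = "last"

    def __post_init__(self) -> None:
        if self.n_dn < 1 or self.n_dp < 1 or self.n_sp < 1:
            raise ValueError("generation counts must be positive")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.egress_from not in ("last", "all"):
            raise ValueError("egress_from must be 'last' or 'all'")
        if self.m_dn is None:
            self.m_dn = [0.1 * i for i in range(1, self.n_dn + 1)]
        if self.m_dp is None:
            self.m_dp = [0.1 * i for i in range(1, self.n_dp + 1)]
        if len(self.m_dn) != self.n_dn or len(self.m_dp) != self.n_dp:
            raise ValueError("m_dn / m_dp must have one rate per generation")
        for seq in (self.m_dn, self.m_dp):
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValueError("differentiation rates must be non-decreasing by generation")
        for name in ("sigma", "d_dn", "d_dp", "d_sp", "s_dp", "e4", "e8"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def _rates(self, spec, n: int, what: str) -> list[float]:
        if isinstance(spec, (int, float)):
            return [float(spec)] * n
        vals = [float(v) for v in spec]
        if len(vals) != n:
            raise ValueError(f"{what} must have {n} entries")
        return vals


def build_conveyor_belt(config: Optional[ConveyorConfig] = None) -> Statechart:
    """Build the staged (conveyor-belt) thymocyte differentiation chart.

    Structure: compound ``DoubleNegative`` with generations DN1..DNn and
    compound ``DoublePositive`` with DP1..DPn; per-generation proliferation
    transitions carry ``offspring 2·delta`` into the next generation;
    differentiation leaves every DN generation (per-substate rates ``mdn_i``)
    and enters ``DoublePositive`` at DP1; natural death is one factored
    transition per compound; SP4/SP8 receive the DP output, and egress to
    the periphery is a SINK transition (provenance "periphery").
    """
    cfg = config or ConveyorConfig()
    params: dict[str, float] = {
        "sigma": cfg.sigma, "delta": cfg.delta,
        "d_dn": cfg.d_dn, "d_dp": cfg.d_dp, "d_sp": cfg.d_sp,
        "s_dp": cfg.s_dp, "e4": cfg.e4, "e8": cfg.e8,
        "f4": cfg.frac_cd4, "f8": 1.0 - cfg.frac_cd4,
    }
    a_dn = cfg._rates(cfg.a_dn, cfg.n_dn, "a_dn")
    a_dp = cfg._rates(cfg.a_dp, cfg.n_dp, "a_dp")
    transitions: list[Transition] = []

    def stage(prefix: str, n: int) -> State:
        return State(
            prefix.replace("DN", "DoubleNegative").replace("DP", "DoublePositive"),
            tuple(State(f"{prefix}{i}") for i in range(1, n + 1)),
            f"{prefix}1",
        )

    dn = stage("DN", cfg.n_dn)
    dp = stage("DP", cfg.n_dp)

    # proliferation: two daughters into the next generation, lost under treatment
    for i in range(1, cfg.n_dn):
        params[f"adn_{i}"] = a_dn[i - 1]
        transitions.append(_t(f"DN{i}", f"DN{i+1}", f"adn_{i}", offspring="2*delta"))
    for i in range(1, cfg.n_dp):
        params[f"adp_{i}"] = a_dp[i - 1]
        transitions.append(_t(f"DP{i}", f"DP{i+1}", f"adp_{i}", offspring="2*delta"))

    # differentiation leaves every generation, faster in later ones,
    # entering the next compound at its first substate
    for i in range(1, cfg.n_dn + 1):
        params[f"mdn_{i}"] = cfg.m_dn[i - 1]
    transitions.append(
        _t("DoubleNegative", "DoublePositive",
           {f"DN{i}": f"mdn_{i}" for i in range(1, cfg.n_dn + 1)})
    )
    for i in range(1, cfg.n_dp + 1):
        params[f"mdp_{i}"] = cfg.m_dp[i - 1]
    dp_rates4 = {f"DP{i}": f"f4 * mdp_{i}" for i in range(1, cfg.n_dp + 1)}
    dp_rates8 = {f"DP{i}": f"f8 * mdp_{i}" for i in range(1, cfg.n_dp + 1)}

    # death: one factored transition per compound
    transitions.append(_t("DoubleNegative", SINK, "d_dn"))
    transitions.append(_t("DoublePositive", SINK, "d_dp"))
    transitions.append(_t("DoublePositive", SINK, "s_dp"))  # selection

    if cfg.n_sp == 1:
        sp4: State = State("SP4")
        sp8: State = State("SP8")
        egress4, egress8 = ["SP4"], ["SP8"]
    else:
        sp4 = State("SP4", tuple(State(f"SP4_{i}") for i in range(1, cfg.n_sp + 1)), "SP4_1")
        sp8 = State("SP8", tuple(State(f"SP8_{i}") for i in range(1, cfg.n_sp + 1)), "SP8_1")
        for i in range(1, cfg.n_sp):
            params.setdefault("a_sp", 0.3)
            transitions.append(_t(f"SP4_{i}", f"SP4_{i+1}", "a_sp", offspring="2*delta"))
            transitions.append(_t(f"SP8_{i}", f"SP8_{i+1}", "a_sp", offspring="2*delta"))
        if cfg.egress_from == "last":
            egress4, egress8 = [f"SP4_{cfg.n_sp}"], [f"SP8_{cfg.n_sp}"]
        else:
            egress4 = [f"SP4_{i}" for i in range(1, cfg.n_sp + 1)]
            egress8 = [f"SP8_{i}" for i in range(1, cfg.n_sp + 1)]

    transitions.append(_t("DoublePositive", "SP4", dp_rates4))
    transitions.append(_t("DoublePositive", "SP8", dp_rates8))
    transitions.append(_t("SP4", SINK, "d_sp"))
    transitions.append(_t("SP8", SINK, "d_sp"))
    for s in egress4:
        transitions.append(_t(s, SINK, "e4"))  # egress to the periphery
    for s in egress8:
        transitions.append(_t(s, SINK, "e8"))

    region = Region(
        "thymocyte",
        (dn, dp, sp4, sp8),
        tuple(transitions),
        initial="DoubleNegative",
    )
    chart = Statechart(
        "conveyor_belt",
        (region,),
        params,
        (Influx("DoubleNegative", parse_rate("sigma")),),
    )
    require_valid(chart)
    return chart
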