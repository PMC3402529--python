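"""Flattening, product expansion, guards, couplings — the compiler core."""

import random
from collections import Counter

import pytest

from popchart import (
    ChartError,
    Influx,
    Region,
    SINK,
    State,
    Statechart,
    Transition,
    count_product_states,
    expand,
    flatten,
    parse_guard,
    parse_rate,
)
from popchart.zoo import build_example

from _bruteforce import enumerate_network
from conftest import random_chart


def entry_multiset(network) -> Counter:
    return Counter(
        (e.from_name, e.to_name, e.rate.source, e.flux_mode) for e in network.fluxes
    )


class TestFlatten:
    def test_per_substate_death_rates(self):
        comp = State("A", (State("A1"), State("A2"), State("A3")), "A1")
        region = Region(
            "r",
            (comp,),
            (Transition("A", SINK, {"A1": parse_rate("d1"), "A2": parse_rate("d2"),
                                    "A3": parse_rate("d3")}),),
            initial="A",
        )
        chart = Statechart("c", (region,), {"d1": 0.1, "d2": 0.2, "d3": 0.3})
        flat = flatten(chart)[0]
        assert {(t.source, t.target, t.rate.source) for t in flat.transitions} == {
            ("A1", SINK, "d1"), ("A2", SINK, "d2"), ("A3", SINK, "d3"),
        }

    def test_entry_redirected_to_initial_substate(self):
        dp = State("DoublePositive", (State("DP1"), State("DP2")), "DP1")
        region = Region(
            "r",
            (State("B"), dp),
            (Transition("B", "DoublePositive", parse_rate("m")),),
            initial="B",
        )
        chart = Statechart("c", (region,), {"m": 1.0})
        flat = flatten(chart)[0]
        assert [(t.source, t.target) for t in flat.transitions] == [("B", "DP1")]

    def test_nested_entry_redirection_recurses(self):
        inner = State("C1", (State("L1"), State("L2")), "L2")
        comp = State("C", (inner, State("L3")), "C1")
        region = Region(
            "r", (State("B"), comp), (Transition("B", "C", parse_rate("m")),), initial="B"
        )
        chart = Statechart("c", (region,), {"m": 1.0})
        assert flatten(chart)[0].transitions[0].target == "L2"

    def test_chart_without_compounds_is_unchanged(self):
        chart = build_example("dn_dp_sp")
        flat = flatten(chart)[0]
        assert flat.leaves == ("DN", "DP", "SP")
        assert [(t.source, t.target, t.rate.source) for t in flat.transitions] == [
            ("DN", "DP", "p1"), ("DP", "SP", "p2"),
        ]

    def test_shared_rate_fans_out_over_all_substates(self):
        comp = State("A", (State("A1"), State("A2")), "A1")
        region = Region("r", (comp, State("B")),
                        (Transition("A", "B", parse_rate("m")),), initial="A")
        chart = Statechart("c", (region,), {"m": 1.0})
        flat = flatten(chart)[0]
        assert {(t.source, t.rate.source) for t in flat.transitions} == {
            ("A1", "m"), ("A2", "m")}


class TestExpand:
    def test_two_independent_regions_four_states_four_entries(self):
        net = expand(build_example("parallel_independent"))
        assert net.n_states == 4
        assert len(net.fluxes) == 4

    def test_lymphocyte_has_eighteen_states(self):
        assert expand(build_example("lymphocyte")).n_states == 18

    def test_guard_removes_exactly_the_blocked_entry(self):
        guarded = expand(build_example("parallel_strong"))
        free = expand(build_example("parallel_independent"))
        assert len(guarded.fluxes) == len(free.fluxes) - 1
        guarded_edges = {(e.from_name, e.to_name) for e in guarded.fluxes}
        free_edges = {(e.from_name, e.to_name) for e in free.fluxes}
        assert free_edges - guarded_edges == {("A|Y", "B|Y")}

    def test_guarded_out_entries_absent_not_zero_rated(self):
        net = expand(build_example("parallel_strong"))
        assert ("A|Y", "B|Y") not in {(e.from_name, e.to_name) for e in net.fluxes}
        # every surviving entry has a genuinely positive rate
        assert all(e.rate.evaluate(net.parameters) > 0 for e in net.fluxes)

    def test_weak_dependency_rates_bound_per_context(self):
        net = expand(build_example("parallel_weak"))
        p = net.parameters
        rates = {
            (e.from_name, e.to_name): e.rate.evaluate(p) for e in net.fluxes
            if e.from_name.endswith("|X")
        }
        assert rates[("A|X", "A|Y")] == pytest.approx(p["kx_a"])
        assert rates[("B|X", "B|Y")] == pytest.approx(p["kx_b"])

    def test_influx_targets_initial_leaves_of_other_regions(self):
        net = expand(build_example("lymphocyte"))
        influx = [e for e in net.fluxes if e.from_name == "EXTERNAL"]
        assert len(influx) == 1
        assert influx[0].to_name == "Naive|LymphNode|G0"
        assert influx[0].flux_mode == "constant"

    def test_influx_context_override(self):
        r1 = Region("r1", (State("A"), State("B")), (), initial="A")
        r2 = Region("r2", (State("X"), State("Y")), (), initial="X")
        chart = Statechart(
            "c", (r1, r2), {"s": 1.0},
            (Influx("B", parse_rate("s"), {"r2": "Y"}),),
        )
        net = expand(chart)
        assert [e.to_name for e in net.fluxes] == ["B|Y"]

    def test_death_removes_whole_product_individual(self):
        # a SINK transition in one track ends the individual regardless of
        # the other coordinates
        r1 = Region("r1", (State("A"),), (Transition("A", SINK, parse_rate("d")),), initial="A")
        r2 = Region("r2", (State("X"), State("Y")),
                    (Transition("X", "Y", parse_rate("k")),), initial="X")
        net = expand(Statechart("c", (r1, r2), {"d": 0.1, "k": 0.2}))
        sinks = {(e.from_name, e.to_name) for e in net.fluxes if e.to_name == SINK}
        assert sinks == {("A|X", SINK), ("A|Y", SINK)}

    def test_state_space_cap_enforced(self):
        regions = tuple(
            Region(f"r{i}", tuple(State(f"S{i}_{j}") for j in range(50)), (),
                   initial=f"S{i}_0")
            for i in range(3)
        )
        with pytest.raises(ChartError, match="cap"):
            expand(Statechart("huge", regions, {}))


class TestCouplings:
    def test_joint_edges_and_no_single_coordinate_firing(self):
        net = expand(build_example("coupled_division"))
        edges = {(e.from_name, e.to_name) for e in net.fluxes}
        assert ("S|T1", "G0|T2") in edges
        assert ("S|T2", "G0|T3") in edges
        # no single-coordinate instantiation of any labeled member
        assert ("S|T1", "G0|T1") not in edges
        assert ("S|T1", "S|T2") not in edges

    def test_end_of_chain_is_disabled(self):
        net = expand(build_example("coupled_division"))
        outgoing_from_end = [e for e in net.fluxes if e.from_name == "S|T3"]
        assert outgoing_from_end == []

    def test_joint_entry_carries_bearer_rate_and_offspring(self):
        net = expand(build_example("coupled_division"))
        joint = next(e for e in net.fluxes if e.from_name == "S|T1")
        assert joint.rate.source == "lam"
        assert joint.offspring.evaluate({}) == 2.0

    def test_single_member_label_behaves_as_ordinary(self):
        r1 = Region("r1", (State("A"), State("B")),
                    (Transition("A", "B", parse_rate("k"), label="solo"),), initial="A")
        r2 = Region("r2", (State("X"),), (), initial="X")
        net = expand(Statechart("c", (r1, r2), {"k": 1.0}))
        assert [(e.from_name, e.to_name) for e in net.fluxes] == [("A|X", "B|X")]

    def test_label_confined_to_one_region_rejected(self):
        r1 = Region(
            "r1",
            (State("A"), State("B"), State("C")),
            (
                Transition("A", "B", parse_rate("k"), label="L"),
                Transition("B", "C", label="L"),
            ),
            initial="A",
        )
        r2 = Region("r2", (State("X"),), (), initial="X")
        chart = Statechart("c", (r1, r2), {"k": 1.0})
        with pytest.raises(ChartError):
            expand(chart)


class TestCountProductStates:
    def test_single_region(self):
        assert count_product_states(build_example("dn_dp_sp")) == 3

    def test_student_is_twenty(self):
        assert count_product_states(build_example("student")) == 20

    def test_lymphocyte_is_eighteen(self):
        assert count_product_states(build_example("lymphocyte")) == 18

    def test_equals_region_leaf_product_on_random_charts(self, rng):
        for _ in range(30):
            chart = random_chart(rng)
            expected = 1
            for r in chart.regions:
                expected *= len(r.leaf_states())
            assert count_product_states(chart) == expected
            assert expand(chart).n_states == expected


class TestProperties:
    def test_guard_pruning_monotonicity(self, rng):
        """Adding a guard never increases the flux-entry count."""
        for _ in range(20):
            chart = random_chart(rng, with_guards=False, max_regions=3)
            if len(chart.regions) < 2:
                continue
            base = len(expand(chart).fluxes)
            # guard the first transition of region 0 on a state of region 1
            r0 = chart.regions[0]
            if not r0.transitions:
                continue
            target = chart.regions[1].leaf_states()[0].name
            guarded_t = list(r0.transitions)
            guarded_t[0] = Transition(
                guarded_t[0].source, guarded_t[0].target, guarded_t[0].rate,
                parse_guard(f"not in({target})"), guarded_t[0].label,
                guarded_t[0].offspring, guarded_t[0].flux_mode,
            )
            guarded = Statechart(
                chart.name,
                (Region(r0.name, r0.states, tuple(guarded_t), r0.initial),)
                + chart.regions[1:],
                chart.parameters, chart.influxes,
            )
            assert len(expand(guarded).fluxes) <= base

    def test_one_region_expansion_isomorphic_to_flat_region(self, rng):
        for _ in range(20):
            chart = random_chart(rng, max_regions=1, with_guards=False,
                                 with_sinks=True, with_influx=True)
            flat = flatten(chart)[0]
            net = expand(chart)
            assert net.state_names() == list(flat.leaves)
            proportional = Counter(
                (e.from_name, e.to_name, e.rate.source)
                for e in net.fluxes if e.from_name != "EXTERNAL"
            )
            expected = Counter(
                (t.source, t.target, t.rate.source)
                for t in flat.transitions if t.source != "ORIGIN"
            )
            assert proportional == expected

    def test_oracle_equivalence_on_random_family(self):
        """expand() agrees entry-for-entry with the independent brute-force
        enumerator over a family of small random charts."""
        rng = random.Random(815)
        for _ in range(120):
            chart = random_chart(rng, max_regions=3, max_leaves=4,
                                 with_guards=True, with_compounds=True,
                                 with_sinks=True, with_influx=True)
            assert entry_multiset(expand(chart)) == enumerate_network(chart), chart.name
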