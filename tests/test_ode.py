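"""Deterministic reading: right-hand-side algebra, closed-form checks,
conservation/linearity properties and CSV round-trips."""

import math

import numpy as np
import pytest

from popchart import (
    Region,
    SINK,
    SimConfig,
    State,
    Statechart,
    Transition,
    build_rhs,
    expand,
    parse_rate,
    read_trajectory_csv,
    simulate_ode,
    write_trajectory_csv,
)
from popchart.ode import SimulationError
from popchart.zoo import build_example

from conftest import random_chart


def single_region(name, states, transitions, params, influxes=()):
    region = Region("r", tuple(State(s) for s in states), tuple(transitions),
                    initial=states[0])
    return Statechart(name, (region,), params, tuple(influxes))


class TestBuildRhs:
    def test_single_transition_appears_twice(self):
        chart = single_region(
            "ab", ["A", "B"], [Transition("A", "B", parse_rate("k"))], {"k": 0.5}
        )
        rhs = build_rhs(expand(chart))
        np.testing.assert_allclose(rhs(0.0, np.array([1.0, 0.0])), [-0.5, 0.5])

    def test_self_loop_offspring_two_nets_plus_ax(self):
        chart = single_region(
            "prolif", ["A"],
            [Transition("A", "A", parse_rate("a"), offspring=parse_rate(2.0))],
            {"a": 0.2},
        )
        rhs = build_rhs(expand(chart))
        np.testing.assert_allclose(rhs(0.0, np.array([10.0])), [2.0])

    def test_mass_action_infection_term(self):
        net = expand(build_example("infection"))
        rhs = build_rhs(net)
        x = np.zeros(3)
        x[net.index["Uninfected"]] = 100.0
        x[net.index["Virus"]] = 50.0
        dx = rhs(0.0, x)
        assert dx[net.index["Uninfected"]] == pytest.approx(-50.0)
        assert dx[net.index["Infected"]] == pytest.approx(50.0)
        assert dx[net.index["Virus"]] == pytest.approx(0.0)

    def test_sink_and_constant_entries(self):
        chart = single_region(
            "od", ["A"],
            [
                Transition("ORIGIN", "A", parse_rate("s"), flux_mode="constant"),
                Transition("A", SINK, parse_rate("d")),
            ],
            {"s": 3.0, "d": 0.5},
        )
        rhs = build_rhs(expand(chart))
        np.testing.assert_allclose(rhs(0.0, np.array([4.0])), [3.0 - 2.0])

    def test_unresolved_parameter_fails_at_build_time(self):
        chart = single_region(
            "ab", ["A", "B"], [Transition("A", "B", parse_rate("k"))], {"k": 0.5}
        )
        net = expand(chart)
        net.parameters.clear()
        with pytest.raises(KeyError, match="k"):
            build_rhs(net)


class TestClosedForms:
    def test_pure_decay_half_life(self):
        chart = single_region(
            "decay", ["A"], [Transition("A", SINK, parse_rate("k"))],
            {"k": math.log(2.0)},
        )
        traj = simulate_ode(expand(chart), init={"A": 1.0}, t_end=1.0)
        assert traj.column("A")[-1] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("method", ["adaptive", "rk4"])
    def test_two_compartment_chain_matches_bateman(self, method):
        """DP(t) = p1(e^{-p1 t} - e^{-p2 t})/(p2 - p1) for DN(0)=1."""
        p1, p2 = 0.5, 0.25
        net = expand(build_example("dn_dp_sp", {"p1": p1, "p2": p2}))
        cfg = SimConfig(method=method, sample_step=0.25)
        traj = simulate_ode(net, init={"DN": 1.0}, t_end=8.0, config=cfg)
        t = traj.times
        expected = p1 * (np.exp(-p1 * t) - np.exp(-p2 * t)) / (p2 - p1)
        np.testing.assert_allclose(traj.column("DP"), expected, atol=1e-6)

    def test_mass_action_matches_fine_step_reference(self):
        """The adaptive solution agrees with a hand-coded RK4 reference at
        1/100th of the sampling step to 1e-5 relative."""
        net = expand(build_example("infection"))
        init = {"Uninfected": 100.0, "Virus": 50.0}
        traj = simulate_ode(net, init=init, t_end=5.0,
                            config=SimConfig(sample_step=0.5))

        # independent fixed-step reference integrator (p = 0.01)
        p = net.parameters["p"]
        iu, ii, iv = (net.index[k] for k in ("Uninfected", "Infected", "Virus"))

        def f(x):
            dx = np.zeros(3)
            flux = p * x[iv] * x[iu]
            dx[iu] -= flux
            dx[ii] += flux
            return dx

        h = 0.5 / 100
        x = np.zeros(3)
        x[iu], x[iv] = 100.0, 50.0
        ref = [x.copy()]
        for step in range(int(5.0 / 0.5)):
            for _ in range(100):
                k1 = f(x); k2 = f(x + h * k1 / 2)
                k3 = f(x + h * k2 / 2); k4 = f(x + h * k3)
                x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            ref.append(x.copy())
        ref = np.array(ref)
        np.testing.assert_allclose(traj.occupancies, ref, rtol=1e-5, atol=1e-8)


class TestTrajectoryProperties:
    def test_conservation_on_closed_random_charts(self, rng):
        """No influx, no SINK, offspring 1 → total occupancy is constant."""
        for _ in range(20):
            chart = random_chart(rng, with_sinks=False, with_influx=False,
                                 with_guards=True)
            net = expand(chart)
            init = np.linspace(1.0, 2.0, net.n_states)
            traj = simulate_ode(net, init=init, t_end=5.0)
            drift = np.abs(traj.total() - traj.total()[0]).max()
            assert drift < 1e-6, chart.name

    def test_linearity_doubling_init_doubles_trajectory(self):
        net = expand(build_example("dn_dp_sp"))
        t1 = simulate_ode(net, init={"DN": 1.0}, t_end=4.0)
        t2 = simulate_ode(net, init={"DN": 2.0}, t_end=4.0)
        np.testing.assert_allclose(t2.occupancies, 2.0 * t1.occupancies,
                                   rtol=1e-7, atol=1e-9)

    def test_first_row_is_initial_condition(self):
        net = expand(build_example("dn_dp_sp"))
        traj = simulate_ode(net, init={"DN": 7.0}, t_end=1.0)
        np.testing.assert_array_equal(
            traj.occupancies[0], [7.0, 0.0, 0.0]
        )

    def test_negative_init_rejected(self):
        net = expand(build_example("dn_dp_sp"))
        with pytest.raises(ValueError):
            simulate_ode(net, init={"DN": -1.0}, t_end=1.0)

    def test_nonpositive_horizon_rejected(self):
        net = expand(build_example("dn_dp_sp"))
        with pytest.raises(ValueError):
            simulate_ode(net, init={"DN": 1.0}, t_end=0.0)


@pytest.fixture(scope="module")
def net():
    return expand(build_example("lymphocyte"))


class TestSymbolicFluxTable:
    """The generated flux table for the three-track lymphocyte chart carries
    exactly the inflow/outflow terms dictated by the diagram for sampled
    compartments — including the cross-track blocking."""

    def test_quiescent_naive_lymph_node_terms(self, net):
        name = "Naive|LymphNode|G0"
        inflow = {(e.from_name, e.rate.source) for e in net.fluxes if e.to_name == name}
        outflow = {(e.to_name, e.rate.source) for e in net.fluxes if e.from_name == name}
        assert inflow == {
            ("EXTERNAL", "sigma"),
            ("Naive|PeripheralTissue|G0", "m_in"),
            ("Naive|LymphNode|SG2M", "lam"),
        }
        assert outflow == {
            ("Effector|LymphNode|G0", "b_n * ligand / (K + pop(Naive) + pop(Memory))"),
            ("SINK", "d_n"),
            ("Naive|PeripheralTissue|G0", "m_out"),
            ("Naive|LymphNode|G1", "k_enter"),
        }

    def test_cycling_compartment_blocks_everything_else(self, net):
        name = "Naive|LymphNode|G1"
        inflow = {(e.from_name, e.rate.source) for e in net.fluxes if e.to_name == name}
        outflow = {(e.to_name, e.rate.source) for e in net.fluxes if e.from_name == name}
        assert inflow == {("Naive|LymphNode|G0", "k_enter")}
        assert outflow == {("Naive|LymphNode|SG2M", "k_cycle")}

    def test_division_returns_two_daughters_to_quiescence(self, net):
        division = [
            e for e in net.fluxes
            if e.from_name == "Effector|LymphNode|SG2M"
        ]
        assert len(division) == 1
        assert division[0].to_name == "Effector|LymphNode|G0"
        assert division[0].offspring.evaluate({}) == 2.0


class TestCsv:
    def test_header_and_roundtrip(self, tmp_path):
        net = expand(build_example("dn_dp_sp"))
        traj = simulate_ode(net, init={"DN": 5.0}, t_end=1.0,
                            config=SimConfig(sample_step=0.5))
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "time,DN,DP,SP"
        assert len(lines) == 1 + len(traj.times)
        back = read_trajectory_csv(path)
        np.testing.assert_array_equal(back.times, traj.times)
        np.testing.assert_array_equal(back.occupancies, traj.occupancies)
        assert back.columns == traj.columns

    def test_empty_trajectory_writes_header_only(self, tmp_path):
        from popchart.ode import Trajectory

        traj = Trajectory(np.empty(0), np.empty((0, 2)), ["A", "B"])
        path = tmp_path / "empty.csv"
        write_trajectory_csv(traj, path)
        assert path.read_text().splitlines() == ["time,A,B"]
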