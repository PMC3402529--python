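"""Deterministic (ODE) reading of a compiled network.

Each proportional flux entry contributes ``-v`` to its source and
``+offspring·v`` to its target, with ``v = rate × X[source]``; constant
entries contribute ``+rate`` to their target only.  A self-entry with
offspring 2 therefore nets ``+rate·X`` — in-place proliferation.  The ODE
right-hand side is the plain sum of these contributions, which is exactly
the "appears twice, negatively on one side and positively on the other"
structure of compartmental equations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .expansion import CompiledNetwork

__all__ = [
    "SimConfig",
    "Trajectory",
    "build_rhs",
    "simulate_ode",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Integrator failure or non-physical (negative) occupancies."""


@dataclass
class SimConfig:
    """Integration configuration.

    method 'adaptive' uses scipy's RK45 with tight tolerances; 'rk4' is a
    fixed-step classic Runge–Kutta for bit-level reproducibility across
    platforms.  ``sample_step`` sets the output grid spacing (dense output in
    between is the solver's business, not the trajectory's).
    """

    method: str = "adaptive"
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_step: float = 0.1
    rk4_step: float = 1e-3


@dataclass
class Trajectory:
    """Time grid plus occupancy matrix over product states."""

    times: np.ndarray
    occupancies: np.ndarray  # shape (len(times), n_states)
    columns: list[str]
    metadata: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        return self.occupancies[:, self.columns.index(name)]

    def total(self) -> np.ndarray:
        return self.occupancies.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancies, columns=self.columns)
        df.insert(0, "time", self.times)
        return df


def build_rhs(
    network: CompiledNetwork, params: Optional[Mapping[str, float]] = None
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the flux table into a derivative operator ``f(t, x) -> dx``.

    All expression symbols are resolved at build time; ``pop()`` references
    are bound to index groups over the product-state vector.
    """
    p = dict(network.parameters)
    if params:
        p.update(params)
    n = network.n_states

    # Pre-resolve everything once; per-call work is arithmetic only.
    compiled = []
    for e in network.fluxes:
        i = network.index[e.from_name] if e.source is not None else None
        j = network.index[e.to_name] if e.target is not None else None
        rate_expr, off_expr = e.rate, e.offspring
        # check symbols now so errors surface at build time
        for name in rate_expr.param_refs() | off_expr.param_refs():
            if name not in p:
                raise KeyError(f"unresolved parameter {name!r} in flux {e.from_name}->{e.to_name}")
        for s in rate_expr.pop_refs() | off_expr.pop_refs():
            if s not in network.state_groups:
                raise KeyError(f"unresolved pop({s}) in flux {e.from_name}->{e.to_name}")
        dynamic = bool(rate_expr.pop_refs() or off_expr.pop_refs())
        if not dynamic:
            rate_val = rate_expr.evaluate(p)
            off_val = off_expr.evaluate(p)
            compiled.append((i, j, e.flux_mode, rate_val, off_val, None, None))
        else:
            compiled.append((i, j, e.flux_mode, None, None, rate_expr, off_expr))

    lookup_factory = network.occupancy_lookup

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros(n)
        lookup = lookup_factory(x)
        for i, j, mode, rate_val, off_val, rate_expr, off_expr in compiled:
            if rate_val is None:
                rate_val = rate_expr.evaluate(p, lookup)
                off_val = off_expr.evaluate(p, lookup)
            if mode == "constant":
                if j is not None:
                    dx[j] += rate_val
                continue
            v = rate_val * x[i]
            dx[i] -= v
            if j is not None:
                dx[j] += off_val * v
        return dx

    return rhs


def _sample_times(t_end: float, step: float) -> np.ndarray:
    n = int(round(t_end / step))
    ts = np.linspace(0.0, n * step, n + 1)
    if ts[-1] < t_end - 1e-12:
        ts = np.append(ts, t_end)
    else:
        ts[-1] = t_end
    return ts


def simulate_ode(
    network: CompiledNetwork,
    params: Optional[Mapping[str, float]] = None,
    init: Optional[Mapping[str, float] | Sequence[float]] = None,
    t_end: float = 10.0,
    config: Optional[SimConfig] = None,
) -> Trajectory:
    """Integrate the network deterministically from ``init`` to ``t_end``.

    ``init`` maps product-state names (or authored leaf names for
    single-region charts — the canonical name of a 1-tuple is the leaf name)
    to occupancies; missing states start at 0.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    config = config or SimConfig()
    x0 = _init_vector(network, init)
    if np.any(x0 < 0):
        raise ValueError("initial occupancies must be non-negative")
    rhs = build_rhs(network, params)
    ts = _sample_times(t_end, config.sample_step)

    if config.method == "rk4":
        xs = _rk4(rhs, x0, ts, config.rk4_step)
        meta = {"method": "rk4", "step": config.rk4_step}
    elif config.method == "adaptive":
        sol = solve_ivp(
            rhs, (0.0, t_end), x0, method="RK45", t_eval=ts,
            rtol=config.rtol, atol=config.atol, dense_output=False,
        )
        if not sol.success:
            raise SimulationError(f"integrator failed: {sol.message}")
        xs = sol.y.T
        meta = {"method": "adaptive", "rtol": config.rtol, "atol": config.atol}
    else:
        raise ValueError(f"unknown method {config.method!r}")

    # tiny undershoot is a solver artifact; anything larger is a model error
    tol = config.atol * 10
    low = xs.min()
    if low < -tol:
        raise SimulationError(
            f"occupancy undershoot {low:.3e} exceeds tolerance {tol:.1e};"
            " the model (not the solver) is producing negative populations"
        )
    xs = np.clip(xs, 0.0, None)
    return Trajectory(ts, xs, network.state_names(), meta)


def _rk4(rhs, x0: np.ndarray, sample_times: np.ndarray, h: float) -> np.ndarray:
    out = np.empty((len(sample_times), len(x0)))
    out[0] = x0
    x = x0.astype(float).copy()
    t = sample_times[0]
    for k in range(1, len(sample_times)):
        t_next = sample_times[k]
        while t < t_next - 1e-12:
            step = min(h, t_next - t)
            k1 = rhs(t, x)
            k2 = rhs(t + step / 2, x + step * k1 / 2)
            k3 = rhs(t + step / 2, x + step * k2 / 2)
            k4 = rhs(t + step, x + step * k3)
            x = x + (step / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
        out[k] = x
    return out


def _init_vector(network: CompiledNetwork, init) -> np.ndarray:
    if init is None:
        return np.zeros(network.n_states)
    if isinstance(init, Mapping):
        x0 = np.zeros(network.n_states)
        for name, v in init.items():
            if name in network.index:
                x0[network.index[name]] = v
            elif name in network.state_groups:
                idxs = network.state_groups[name]
                if len(idxs) != 1:
                    raise KeyError(
                        f"initial occupancy for {name!r} is ambiguous over"
                        f" {len(idxs)} product states; use a product-state name"
                    )
                x0[idxs[0]] = v
            else:
                raise KeyError(f"unknown state {name!r} in initial occupancies")
        return x0
    arr = np.asarray(init, dtype=float)
    if arr.shape != (network.n_states,):
        raise ValueError(f"init vector must have length {network.n_states}")
    return arr.copy()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_trajectory_csv(trajectory: Trajectory, destination: str | Path) -> None:
    """Write ``time`` + one column per product state, full float precision."""
    with open(destination, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time"] + trajectory.columns)
        for t, row in zip(trajectory.times, trajectory.occupancies):
            w.writerow([repr(float(t))] + [repr(float(v)) for v in row])


def read_trajectory_csv(source: str | Path) -> Trajectory:
    with open(source, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        rows = [[float(v) for v in row] for row in r]
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(header)))
    return Trajectory(data[:, 0], data[:, 1:], header[1:])
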