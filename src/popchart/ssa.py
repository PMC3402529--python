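"""Exact stochastic (Gillespie direct-method) reading of a compiled network.

The same flux table that defines the ODE right-hand side defines event
propensities: a proportional entry has propensity ``rate × count(source)``,
a constant entry has propensity ``rate``.  An event removes one individual
from the source and deposits ``offspring`` individuals (a non-negative
integer; 2 for a division) at the target.  For linear (pop()-free) rates the
ensemble mean of this process is exactly the ODE solution, which is the
cross-check the test-suite leans on.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .expansion import CompiledNetwork
from .ode import Trajectory, _init_vector, _sample_times

__all__ = ["simulate_ssa", "ensemble_mean"]


def _offspring_count(value: float, provenance) -> int:
    k = round(value)
    if abs(value - k) > 1e-9 or k < 0:
        raise ValueError(
            f"offspring {value!r} of flux {provenance} is not a non-negative"
            " integer; stochastic events need whole individuals"
        )
    return int(k)


def simulate_ssa(
    network: CompiledNetwork,
    params: Optional[Mapping[str, float]] = None,
    init: Optional[Mapping[str, float] | Sequence[float]] = None,
    t_end: float = 10.0,
    seed: Optional[int] = None,
    sample_step: float = 0.1,
) -> Trajectory:
    """Run one exact event-driven realization, sampled on a fixed grid.

    Identical ``(network, params, init, seed)`` yields an identical event
    sequence; ``seed`` is therefore mandatory in any scripted use.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    p = dict(network.parameters)
    if params:
        p.update(params)
    x0 = _init_vector(network, init)
    if np.any(x0 < 0) or np.any(np.abs(x0 - np.round(x0)) > 1e-9):
        raise ValueError("stochastic initial occupancies must be non-negative integers")
    counts = np.round(x0).astype(np.int64)
    rng = np.random.default_rng(seed)

    entries = []
    for e in network.fluxes:
        i = network.index[e.from_name] if e.source is not None else None
        j = network.index[e.to_name] if e.target is not None else None
        dynamic = bool(e.rate.pop_refs() or e.offspring.pop_refs())
        rate_val = None if e.rate.pop_refs() else e.rate.evaluate(p)
        off_val = None if e.offspring.pop_refs() else e.offspring.evaluate(p)
        entries.append((i, j, e.flux_mode == "constant", rate_val, off_val, e))
    lookup_factory = network.occupancy_lookup

    ts = _sample_times(t_end, sample_step)
    out = np.empty((len(ts), len(counts)), dtype=float)
    out[0] = counts
    t = 0.0
    next_sample = 1
    n_entries = len(entries)
    prop = np.empty(n_entries)

    while next_sample < len(ts):
        lookup = lookup_factory(counts) if any(e[3] is None for e in entries) else None
        for k, (i, j, const, rate_val, off_val, e) in enumerate(entries):
            r = rate_val if rate_val is not None else e.rate.evaluate(p, lookup)
            prop[k] = r if const else r * counts[i]
        if np.any(prop < 0):
            k = int(np.argmin(prop))
            raise ValueError(
                f"negative propensity {prop[k]:.3e} for flux"
                f" {entries[k][5].from_name}->{entries[k][5].to_name}"
            )
        a0 = prop.sum()
        if a0 <= 0.0:
            break  # nothing can happen again; hold state to the end
        t += rng.exponential(1.0 / a0)
        while next_sample < len(ts) and ts[next_sample] <= t:
            out[next_sample] = counts
            next_sample += 1
        if t >= t_end:
            break
        k = int(np.searchsorted(np.cumsum(prop), rng.random() * a0, side="right"))
        k = min(k, n_entries - 1)
        i, j, const, rate_val, off_val, e = entries[k]
        if off_val is None:
            off_val = e.offspring.evaluate(p, lookup_factory(counts))
        noff = _offspring_count(off_val, f"{e.from_name}->{e.to_name}")
        if not const:
            counts[i] -= 1
            assert counts[i] >= 0, "event fired from an empty state"
        if j is not None:
            counts[j] += noff

    out[next_sample:] = counts
    return Trajectory(
        ts,
        out,
        network.state_names(),
        {"method": "ssa", "seed": seed, "sample_step": sample_step},
    )


def ensemble_mean(
    network: CompiledNetwork,
    params: Optional[Mapping[str, float]] = None,
    init: Optional[Mapping[str, float] | Sequence[float]] = None,
    t_end: float = 10.0,
    n_runs: int = 1,
    seed: Optional[int] = None,
    sample_step: float = 0.1,
    return_sem: bool = False,
):
    """Pointwise mean over ``n_runs`` independent realizations.

    Replicate seeds are drawn deterministically from the master seed, so the
    whole ensemble is reproducible from one integer.  With
    ``return_sem=True`` also returns the matrix of standard errors of the
    mean (zero where runs never differ).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    acc = None
    acc2 = None
    times = None
    cols = None
    for s in child_seeds:
        tr = simulate_ssa(network, params, init, t_end, int(s), sample_step)
        if acc is None:
            acc = np.zeros_like(tr.occupancies)
            acc2 = np.zeros_like(tr.occupancies)
            times, cols = tr.times, tr.columns
        acc += tr.occupancies
        acc2 += tr.occupancies**2
    mean = acc / n_runs
    meta = {"method": "ssa-ensemble", "seed": seed, "n_runs": n_runs}
    traj = Trajectory(times, mean, cols, meta)
    if not return_sem:
        return traj
    var = np.maximum(acc2 / n_runs - mean**2, 0.0)
    sem = np.sqrt(var / n_runs)
    return traj, sem
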