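"""Gillespie direct-method simulation, the independent oracle.

The stochastic simulation algorithm draws exponential waiting times from
the total propensity and picks the firing reaction proportionally to its
propensity; jump-kernel reactions (e.g. binomial division) sample their
destination state.  Long-run, time-weighted occupancy converges to the
steady-state CME solution and serves as an independent cross-check of the
direct solver and of the Gibbs sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import DistributionGrid, ModelError, ReactionNetwork, StateSpace

__all__ = ["Trajectory", "gillespie_simulate", "occupancy_distribution"]


@dataclass
class Trajectory:
    """Event times and post-event states of one stochastic realization.

    ``times[0] = 0`` with the initial state; ``t_end`` is the requested
    horizon (or the absorption time).  ``absorbed`` flags an all-zero
    propensity state reached before ``t_max``.
    """

    times: np.ndarray
    states: np.ndarray
    t_end: float
    seed: int | None
    absorbed: bool = False


def _compile_rate_function(network: ReactionNetwork):
    """Generate one scalar function returning all propensities as a tuple,
    with parameter values inlined (fast path for the event loop)."""
    names = network.species
    exprs = ", ".join(f"({r.propensity})" for r in network.reactions)
    src = f"def _rates({', '.join(names)}):\n    return ({exprs},)"
    env: dict = {"__builtins__": {}}
    env.update(network.parameters)
    env.update(
        exp=math.exp, log=math.log, sqrt=math.sqrt, abs=abs, min=min, max=max
    )
    exec(src, env)  # expressions already validated by the network
    return env["_rates"]


class _UniformBuffer:
    """Blocked uniform draws (cheap per-event randomness)."""

    def __init__(self, rng: np.random.Generator, block: int = 1 << 15):
        self.rng = rng
        self.block = block
        self.buf = rng.random(block)
        self.pos = 0

    def next(self) -> float:
        if self.pos >= self.block:
            self.buf = self.rng.random(self.block)
            self.pos = 0
        u = self.buf[self.pos]
        self.pos += 1
        return u


def gillespie_simulate(
    network: ReactionNetwork,
    init,
    t_max: float,
    seed: int | None = None,
    max_events: int | None = None,
) -> Trajectory:
    """Simulate one trajectory of the network up to time ``t_max``.

    Deterministic under ``seed``.  If every propensity vanishes the state
    is absorbing and the trajectory ends early with ``absorbed=True``.
    """
    if t_max <= 0:
        raise ModelError("t_max must be positive")
    rng = np.random.default_rng(seed)
    uni = _UniformBuffer(rng)
    rates_fn = _compile_rate_function(network)
    d = network.n_species
    reactions = network.reactions
    changes = [
        tuple(int(c) for c in r.change) if r.change is not None else None
        for r in reactions
    ]
    kernels = [getattr(r, "_kernel", None) for r in reactions]
    state = [int(x) for x in np.asarray(init).reshape(d)]
    cap = 1 << 14
    times = np.empty(cap)
    states = np.empty((cap, d), dtype=np.int64)
    times[0] = 0.0
    states[0] = state
    k = 1
    t = 0.0
    absorbed = False
    n_events = 0
    while t < t_max:
        rates = rates_fn(*state)
        total = 0.0
        for a in rates:
            if a < 0:
                raise ModelError("negative propensity during simulation")
            total += a
        if total <= 0.0:
            absorbed = True  # state persists to the horizon
            t = t_max
            break
        t += -math.log(1.0 - uni.next()) / total
        if t >= t_max:
            break
        pick = total * uni.next()
        acc = 0.0
        j = 0
        for j, a in enumerate(rates):
            acc += a
            if pick < acc:
                break
        ch = changes[j]
        if ch is not None:
            state = [s + c for s, c in zip(state, ch)]
        else:
            kern = kernels[j]
            if hasattr(kern, "sample"):
                state = [int(x) for x in kern.sample(np.asarray(state), rng)]
            else:
                dests, probs = reactions[j].destinations(np.asarray(state))
                state = [int(x) for x in dests[rng.choice(len(probs), p=probs)]]
        if k >= cap:
            cap *= 2
            times = np.resize(times, cap)
            states = np.resize(states, (cap, d))
        times[k] = t
        states[k] = state
        k += 1
        n_events += 1
        if max_events is not None and n_events >= max_events:
            break
    return Trajectory(
        times=times[:k].copy(),
        states=states[:k].copy(),
        t_end=min(t, t_max) if (max_events and n_events >= max_events) else t_max,
        seed=seed,
        absorbed=absorbed,
    )


def occupancy_distribution(
    trajectory: Trajectory, burn_in_time: float, space: StateSpace
) -> DistributionGrid:
    """Time-weighted state occupancy after a burn-in window.

    States outside the analysis box are binned into the nearest boundary
    cell; the excess residence-time fraction is reported on the returned
    grid as ``out_of_box_mass``.
    """
    if trajectory.t_end <= burn_in_time:
        raise ModelError("no post-burn-in window in the trajectory")
    t = np.append(trajectory.times, trajectory.t_end)
    dwell = np.diff(t)
    # clip each dwell interval to [burn_in_time, t_end]
    start = np.maximum(trajectory.times, burn_in_time)
    end = np.minimum(np.append(trajectory.times[1:], trajectory.t_end), trajectory.t_end)
    dwell = np.clip(end - start, 0.0, None)
    clipped = np.clip(trajectory.states, 0, space.upper)
    out_mask = np.any(trajectory.states != clipped, axis=1)
    excess = float(dwell[out_mask].sum() / dwell.sum())
    mass = np.zeros(space.n_states)
    np.add.at(mass, space.index_of(clipped), dwell)
    grid = DistributionGrid(space, mass)
    grid.out_of_box_mass = excess
    return grid
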