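"""Modified Gibbs sampling (MGS) of steady-state CME distributions.

Ordinary Gibbs sampling of a steady-state molecule-number distribution
draws each species in turn from its conditional distribution given the
others.  Here the conditional along a lattice line is built from the
per-species detailed-balance approximation: a unit step up in species i
multiplies the probability by a_s,i(x) / a_d,i(x + e_i), where a_s,i and
a_d,i are the summed propensities of reactions producing / consuming one
molecule of species i.  For a one-species birth-death chain this is exact;
in general it is an approximation whose quality is measured by
:func:`detailed_balance_error`.

Plain axis-aligned Gibbs gets stuck in one mode of a multimodal
distribution.  The modification is a random rotation of the sampling axes
at every cycle: a slope m with tan^-1(m) uniform on (-90, 90) degrees
defines two perpendicular lines through the current point, rounded to the
integer lattice, and the two line coordinates are sampled instead of the
species axes.  Because the rotated proposal is symmetric
(P(x'|x) = P(x|x')), a sample from the target distribution stays
distributed according to it after a cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import DistributionGrid, ModelError, ReactionNetwork, StateSpace

__all__ = [
    "RotatedAxes",
    "SampleSet",
    "axis_line",
    "conditional_line_distribution",
    "draw_rotated_axes",
    "mgs_cycle",
    "mgs_sample",
    "detailed_balance_error",
    "deterministic_fixed_points",
]

#: slopes steeper than this are treated as vertical (axis-aligned swap)
_SLOPE_CAP = 1e9


@dataclass
class RotatedAxes:
    """A pair of perpendicular rounded lattice lines through ``anchor``."""

    anchor: np.ndarray
    slope: float
    lines: tuple[np.ndarray, np.ndarray]  # each (L, d) int, ordered


@dataclass
class SampleSet:
    """Ordered post-burn-in states with reproducibility metadata."""

    states: np.ndarray  # (n, d) int
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.states.shape[0]

    def mean(self) -> np.ndarray:
        return self.states.mean(axis=0)

    def std(self) -> np.ndarray:
        return self.states.std(axis=0)

    def histogram(self, space: StateSpace) -> DistributionGrid:
        """Empirical distribution of the samples on a lattice."""
        counts = np.zeros(space.n_states)
        idx = space.index_of(np.clip(self.states, 0, space.upper))
        np.add.at(counts, idx, 1.0)
        return DistributionGrid(space, counts)


# ---------------------------------------------------------------------------
# conditional distributions along lattice lines


def axis_line(space: StateSpace, state: np.ndarray, i: int) -> np.ndarray:
    """The full axis-aligned lattice line through ``state`` along species i."""
    state = np.asarray(state, dtype=int)
    n = space.upper[i] + 1
    line = np.tile(state, (n, 1))
    line[:, i] = np.arange(n)
    return line


def _log_mass_along_line(network: ReactionNetwork, line: np.ndarray) -> np.ndarray:
    """Unnormalized log-mass at each line point, chained from consecutive
    detailed-balance ratios; inter-point steps are decomposed into unit
    axis moves in species order."""
    l, d = line.shape
    if l == 1:
        return np.zeros(1)
    deltas = np.diff(line, axis=0)
    pair_lr = np.zeros(l - 1)
    e = np.eye(d, dtype=int)
    for i in range(d):
        c = deltas[:, i]
        if not np.any(c):
            continue
        for s in (1, -1):
            pairs = np.nonzero(s * c > 0)[0]
            if pairs.size == 0:
                continue
            counts = (s * c[pairs]).astype(int)
            rep = np.repeat(pairs, counts)
            # within-pair move number 0..count-1
            offs = np.arange(rep.size) - np.repeat(np.cumsum(counts) - counts, counts)
            # state before the move: species < i already advanced to the
            # next line point, species i partway, species > i untouched
            start = line[pairs].copy()
            start[:, :i] = line[pairs + 1][:, :i]
            x = np.repeat(start, counts, axis=0)
            x[:, i] += s * offs
            # up:   log a_s,i(x) - log a_d,i(x+e_i)
            # down: log a_d,i(x) - log a_s,i(x-e_i)
            both = np.concatenate([x, x + s * e[i]], axis=0)
            a_s, a_d = network.step_propensities(both, i)
            num, den = (a_s, a_d) if s == 1 else (a_d, a_s)
            k = x.shape[0]
            with np.errstate(divide="ignore"):
                lr = np.log(num[:k]) - np.log(den[k:])
            np.add.at(pair_lr, rep, np.where(np.isnan(lr), -np.inf, lr))
    logmass = np.concatenate([[0.0], np.cumsum(pair_lr)])
    return np.where(np.isnan(logmass), -np.inf, logmass)


def conditional_line_distribution(
    network: ReactionNetwork, anchor: np.ndarray, line: np.ndarray
) -> np.ndarray:
    """Normalized probability mass over the ordered points of ``line``.

    ``anchor`` must be one of the line points (the current sampler state);
    it fixes the reference point of the chained ratios, though the
    normalized result does not depend on it.  A zero degradation rate
    against a positive synthesis rate makes mass accumulate at the
    boundary point of the line; if both rates vanish the line terminates
    (zero mass beyond that step).
    """
    line = np.asarray(line, dtype=int)
    anchor = np.asarray(anchor, dtype=int)
    if not np.any(np.all(line == anchor, axis=1)):
        raise ModelError("anchor point is not on the line")
    logmass = _log_mass_along_line(network, line)
    top = logmass.max()
    if math.isinf(top) and top > 0:
        p = np.isposinf(logmass).astype(float)
    elif math.isinf(top):  # all -inf: no information, fall back to anchor
        p = np.all(line == anchor, axis=1).astype(float)
    else:
        p = np.exp(logmass - top)
    return p / p.sum()


# ---------------------------------------------------------------------------
# rotated axes


def _rounded_line(
    space: StateSpace,
    state: np.ndarray,
    free: int,
    dep: int,
    slope: float,
) -> np.ndarray:
    """Lattice line through ``state`` varying species ``free``, with the
    ``dep`` coordinate following at the given slope, rounded to integers;
    points outside the box are dropped."""
    state = np.asarray(state, dtype=int)
    t = np.arange(space.upper[free] + 1)
    w = np.rint(state[dep] + slope * (t - state[free])).astype(int)
    ok = (w >= 0) & (w <= space.upper[dep])
    line = np.tile(state, (int(ok.sum()), 1))
    line[:, free] = t[ok]
    line[:, dep] = w[ok]
    return line


def draw_rotated_axes(
    anchor: np.ndarray,
    space: StateSpace,
    rng: np.random.Generator,
    pair: tuple[int, int] = (0, 1),
) -> RotatedAxes:
    """Random rotation of the sampling axes for a species pair.

    The rotation angle tan^-1(m) is uniform on (-90, 90) degrees; the two
    axes have slopes m and -1/m in the (pair[0], pair[1]) plane and pass
    through ``anchor`` exactly.  Near-vertical slopes degenerate into the
    swapped axis-aligned pair.
    """
    anchor = np.asarray(anchor, dtype=int)
    p, q = pair
    phi = rng.uniform(-math.pi / 2, math.pi / 2)
    m = math.tan(phi)
    if not math.isfinite(m) or abs(m) > _SLOPE_CAP:
        line1 = axis_line(space, anchor, q)
        line2 = axis_line(space, anchor, p)
        return RotatedAxes(anchor, math.inf, (line1, line2))
    line1 = _rounded_line(space, anchor, free=p, dep=q, slope=m)
    if m == 0.0:
        line2 = axis_line(space, anchor, q)
    else:
        line2 = _rounded_line(space, anchor, free=q, dep=p, slope=-1.0 / m)
    return RotatedAxes(anchor, m, (line1, line2))


def _axes_lines_through(
    space: StateSpace, state: np.ndarray, pair: tuple[int, int], m: float
) -> tuple:
    """Re-anchor the two rotated axes of slope ``m`` at ``state``."""
    p, q = pair
    if not math.isfinite(m) or abs(m) > _SLOPE_CAP:
        return axis_line(space, state, q), axis_line(space, state, p)
    line1 = _rounded_line(space, state, free=p, dep=q, slope=m)
    line2 = (
        axis_line(space, state, q)
        if m == 0.0
        else _rounded_line(space, state, free=q, dep=p, slope=-1.0 / m)
    )
    return line1, line2


# ---------------------------------------------------------------------------
# the sampler


def _sample_line(
    network: ReactionNetwork,
    line: np.ndarray,
    anchor: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    p = conditional_line_distribution(network, anchor, line)
    cum = np.cumsum(p)
    return line[int(np.searchsorted(cum, rng.random() * cum[-1], side="right").clip(0, len(p) - 1))]


def mgs_cycle(
    network: ReactionNetwork,
    space: StateSpace,
    state: np.ndarray,
    rng: np.random.Generator,
    rotate: bool = True,
) -> np.ndarray:
    """One full MGS cycle from ``state``; returns the new state.

    With rotation (and at least two species) a random species pair is
    resampled along a randomly rotated pair of lattice lines, both passing
    through the current point; all remaining species are sampled along
    their axis lines.  Without rotation every species is sampled along its
    axis line in species order.
    """
    d = space.n_species
    state = np.asarray(state, dtype=int).copy()
    if rotate and d >= 2:
        if d == 2:
            pair = (0, 1)
        else:
            pq = rng.choice(d, size=2, replace=False)
            pair = (int(pq[0]), int(pq[1]))
        phi = rng.uniform(-math.pi / 2, math.pi / 2)
        m = math.tan(phi)
        line1, _ = _axes_lines_through(space, state, pair, m)
        state = _sample_line(network, line1, state, rng)
        _, line2 = _axes_lines_through(space, state, pair, m)
        state = _sample_line(network, line2, state, rng)
        for i in range(d):
            if i in pair:
                continue
            state = _sample_line(network, axis_line(space, state, i), state, rng)
    else:
        for i in range(d):
            state = _sample_line(network, axis_line(space, state, i), state, rng)
    return state


def mgs_sample(
    network: ReactionNetwork,
    space: StateSpace,
    n: int,
    burn_in: int = 1000,
    seed: int | None = None,
    rotate: bool = True,
    init="deterministic-mode",
    mode_weights=None,
) -> SampleSet:
    """Draw ``n`` post-burn-in MGS samples of the steady-state distribution.

    ``init`` is a starting state or the string ``"deterministic-mode"``,
    which starts at a fixed point of the deterministic rate equations.
    ``mode_weights``, a list of ``(weight, init_state)`` pairs, samples
    each mode in a separate chain and pools the results with the given
    weights -- the strategy for systems whose modes are effectively
    disconnected under intrinsic noise alone.
    """
    if n <= 0:
        raise ModelError("n must be positive")
    rng = np.random.default_rng(seed)
    if mode_weights is not None:
        weights = np.array([float(w) for w, _ in mode_weights])
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ModelError("mode weights must be nonnegative and not all zero")
        weights = weights / weights.sum()
        counts = np.floor(weights * n).astype(int)
        counts[-1] += n - counts.sum()
        parts, labels = [], []
        for k, ((_, mode_init), nk) in enumerate(zip(mode_weights, counts)):
            if nk == 0:
                continue
            sub = mgs_sample(
                network,
                space,
                int(nk),
                burn_in=burn_in,
                seed=int(rng.integers(2**31 - 1)),
                rotate=rotate,
                init=mode_init,
            )
            parts.append(sub.states)
            labels.append(np.full(int(nk), k))
        return SampleSet(
            np.concatenate(parts),
            metadata={
                "seed": seed,
                "burn_in": burn_in,
                "rotate": rotate,
                "mode_weights": [float(w) for w, _ in mode_weights],
                "mode_labels": np.concatenate(labels),
            },
        )
    if isinstance(init, str):
        if init != "deterministic-mode":
            raise ModelError(f"unknown init {init!r}")
        fps = deterministic_fixed_points(network, space)
        state = fps[0]
    else:
        state = np.asarray(init, dtype=int)
        if not (np.all(state >= 0) and np.all(state <= space.upper)):
            raise ModelError(f"initial state {state} outside the box")
    out = np.empty((n, space.n_species), dtype=int)
    for c in range(burn_in + n):
        state = mgs_cycle(network, space, state, rng, rotate=rotate)
        if c >= burn_in:
            out[c - burn_in] = state
    return SampleSet(
        out, metadata={"seed": seed, "burn_in": burn_in, "rotate": rotate}
    )


# ---------------------------------------------------------------------------
# diagnostics and helpers


def detailed_balance_error(
    network: ReactionNetwork, p_direct: DistributionGrid
) -> dict[str, float]:
    """Probability-weighted average relative error of the detailed-balance
    approximation, per species.

    For species i the true one-step ratio r_true = P(x+e_i)/P(x) is
    compared with the detailed-balance ratio
    r_db = a_s,i(x)/a_d,i(x+e_i); the error is the P(x)-weighted average
    of |r_db - r_true| / r_true over states where both ratios are defined
    and positive, with the weights renormalized over the included states.
    Species without both a one-step synthesis and a one-step degradation
    channel are absent from the result.
    """
    space = p_direct.space
    if space.scale != 1:
        raise ModelError("detailed-balance diagnostic requires an unscaled grid")
    states = space.states()
    grid = p_direct.grid
    out: dict[str, float] = {}
    for i, name in enumerate(network.species):
        up, down = network.unit_step_reactions(i)
        if not up or not down:
            continue
        a_s, a_d = network.step_propensities(states, i)
        a_s = a_s.reshape(space.shape)
        a_d = a_d.reshape(space.shape)
        sl_lo = [slice(None)] * space.n_species
        sl_hi = [slice(None)] * space.n_species
        sl_lo[i] = slice(0, -1)
        sl_hi[i] = slice(1, None)
        p_lo = grid[tuple(sl_lo)]
        p_hi = grid[tuple(sl_hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            r_true = p_hi / p_lo
            r_db = a_s[tuple(sl_lo)] / a_d[tuple(sl_hi)]
            included = (
                np.isfinite(r_true) & (r_true > 0) & np.isfinite(r_db) & (r_db >= 0)
            )
            err = np.abs(r_db - r_true) / r_true
        w = np.where(included, p_lo, 0.0)
        total = w.sum()
        if total <= 0:
            continue
        out[name] = float(np.sum(w[included] * err[included]) / total)
    return out


def deterministic_fixed_points(
    network: ReactionNetwork, space: StateSpace, max_points: int | None = None
) -> list[np.ndarray]:
    """Stable fixed points of the deterministic rate equations, rounded to
    the lattice.

    The drift sums a_j(x) * v_j over fixed-change reactions; it is relaxed
    by damped iteration from every box corner and the centre, and distinct
    converged points are returned (modes of the distribution, used to
    initialize the sampler).  Jump-kernel reactions do not contribute.
    """
    d = space.n_species
    changes = np.array(
        [r.change for r in network.reactions if r.change is not None], dtype=float
    )
    fixed_idx = [j for j, r in enumerate(network.reactions) if r.change is not None]
    if changes.size == 0:
        raise ModelError("no fixed-change reactions: cannot build a drift field")

    def drift(x):
        a = network.propensity_matrix(np.clip(x, 0, space.upper)[None, :])[0]
        return a[fixed_idx] @ changes

    starts = [np.array(c, dtype=float) for c in np.ndindex(*(2,) * d)]
    starts = [s * space.upper for s in starts]
    starts.append(space.upper / 2.0)
    found: list[np.ndarray] = []
    for x0 in starts:
        x = x0.astype(float)
        for _ in range(4000):
            f = drift(x)
            step = 0.1 * f
            nrm = np.max(np.abs(step))
            if nrm > 1.0:  # keep the damped iteration stable
                step = step / nrm
            x = np.clip(x + step, 0, space.upper)
            if np.max(np.abs(f)) < 1e-9:
                break
        xi = np.rint(x).astype(int)
        if any(np.array_equal(xi, g) for g in found):
            continue
        # keep only stable points: finite-difference Jacobian of the drift
        h = 1e-4
        jac = np.empty((d, d))
        for a in range(d):
            dx = np.zeros(d)
            dx[a] = h
            jac[:, a] = (drift(x + dx) - drift(x - dx)) / (2 * h)
        if np.max(np.linalg.eigvals(jac).real) < 1e-6:
            found.append(xi)
    found.sort(key=lambda s: tuple(-s))
    if max_points is not None:
        found = found[:max_points]
    return found
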