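"""Steady-state solution of the chemical master equation.

The CME for a truncated network is a linear system ``M P = 0`` where ``M``
is the rate (generator) matrix over enumerated states: entry (x', x)
accumulates a_j(x) * kernel_j(x -> x') over reactions j, and the diagonal
removes the total outflow restricted to in-box destinations.  The steady
state is the normalized null vector, obtained here by replacing one
balance row with the normalization row sum(P) = 1 and solving the sparse
nonsingular system.

For the one-species birth-death chain the steady state has the closed
product form P(n) ∝ prod_{j=1..n} a_s(j-1)/a_d(j); with constant synthesis
k_s and linear degradation k_d*n this is Poisson with mean k_s/k_d.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import poisson

from .network import DistributionGrid, ModelError, ReactionNetwork, StateSpace

__all__ = [
    "SizeError",
    "build_generator",
    "solve_steady_state",
    "birth_death_analytic",
    "poisson_constitutive",
]

#: refuse to enumerate lattices beyond this many points
MAX_STATES = 5_000_000

#: acceptable steady-state residual max|M P|
RESIDUAL_TOL = 1e-9


class SizeError(ModelError):
    """State space too large to enumerate."""


def _assemble(network: ReactionNetwork, space: StateSpace, S: int) -> sp.csc_matrix:
    """Shared generator assembly.  Fixed-change reactions send x to
    x + S*v_j at rate a_j(x); jump-kernel reactions (S=1 only) spread
    a_j(x) over their destination mass.  Out-of-box destinations get zero
    rate and contribute nothing to the diagonal (reflecting truncation)."""
    if space.n_states > MAX_STATES:
        raise SizeError(
            f"state space has {space.n_states} points (> {MAX_STATES}); "
            "increase the scale factor or use the Gibbs sampler"
        )
    states = space.states()
    n = space.n_states
    src = np.arange(n)
    a = network.propensity_matrix(states)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for j, r in enumerate(network.reactions):
        if r.change is not None:
            dest = states + S * r.change
            ok = np.all((dest >= 0) & (dest <= space.upper), axis=1)
            ok &= a[:, j] > 0
            rows.append(space.index_of(dest[ok]))
            cols.append(src[ok])
            vals.append(a[ok, j])
            rows.append(src[ok])
            cols.append(src[ok])
            vals.append(-a[ok, j])
        else:
            if S != 1:
                raise ModelError(
                    f"reaction '{r.name}': jump-kernel reactions are not "
                    "supported on a scaled lattice (S>1)"
                )
            for s in src:
                if a[s, j] <= 0:
                    continue
                dests, probs = r.destinations(states[s])
                ok = np.all((dests >= 0) & (dests <= space.upper), axis=1)
                didx = space.index_of(dests[ok])
                rows.append(didx)
                cols.append(np.full(didx.shape, s))
                vals.append(a[s, j] * probs[ok])
                rows.append(np.array([s]))
                cols.append(np.array([s]))
                vals.append(np.array([-a[s, j] * probs[ok].sum()]))
    if rows:
        m = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        m = sp.coo_matrix((n, n))
    return m.tocsc()


def build_generator(network: ReactionNetwork, space: StateSpace) -> sp.csc_matrix:
    """Sparse rate matrix of the truncated CME (columns sum to zero)."""
    return _assemble(network, space, S=space.scale)


def solve_steady_state(
    matrix: sp.spmatrix, space: StateSpace | None = None
) -> DistributionGrid | np.ndarray:
    """Normalized null vector of a generator matrix.

    Returns a :class:`DistributionGrid` when ``space`` is given, else the
    raw probability vector.  Tiny negative entries (> -1e-12 before
    normalization) are clipped to zero; anything more negative, or a
    residual above ``RESIDUAL_TOL``, raises (typically a disconnected
    chain under the chosen truncation -- check the bounds).
    """
    m = sp.csc_matrix(matrix)
    n = m.shape[0]
    a = m.tolil(copy=True)
    a[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            p = spla.spsolve(a.tocsc(), b)
        except (spla.MatrixRankWarning, RuntimeError) as exc:
            raise ModelError(
                "steady-state system is singular beyond one null dimension "
                "(disconnected chain?) -- check the truncation bounds"
            ) from exc
    if not np.all(np.isfinite(p)):
        raise ModelError(
            "steady-state solve produced non-finite entries -- check the bounds"
        )
    scale = p.sum()
    if scale <= 0:
        raise ModelError("steady-state solve produced a non-positive vector")
    if np.min(p) / scale < -1e-12:
        raise ModelError(
            f"steady-state solution has negative mass {np.min(p) / scale:g}; "
            "the chain may be disconnected under the truncation -- check bounds"
        )
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    residual = float(np.max(np.abs(m @ p)))
    if residual > RESIDUAL_TOL:
        raise ModelError(
            f"steady-state residual {residual:g} exceeds {RESIDUAL_TOL:g}; "
            "check the truncation bounds"
        )
    if space is None:
        return p
    return DistributionGrid(space, p)


def birth_death_analytic(
    a_s: Callable[[int], float], a_d: Callable[[int], float], n_max: int
) -> DistributionGrid:
    """Closed-form steady state of a 1-D birth-death chain on [0, n_max].

    ``P(n) ∝ prod_{j=1..n} a_s(j-1)/a_d(j)``, normalized.  Detailed balance
    is exact for this chain, so this equals the matrix solve on the same
    truncation.
    """
    logw = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        down = float(a_d(n))
        if down <= 0:
            raise ZeroDivisionError(
                f"degradation rate a_d({n}) = {down} is not positive"
            )
        up = float(a_s(n - 1))
        if up < 0:
            raise ModelError(f"negative synthesis rate a_s({n - 1})")
        with np.errstate(divide="ignore"):
            logw[n] = logw[n - 1] + (np.log(up) - np.log(down))
    logw -= logw.max()
    w = np.exp(logw)
    return DistributionGrid(StateSpace([n_max]), w)


def poisson_constitutive(k_s: float, k_d: float, n_max: int) -> DistributionGrid:
    """Steady state of constitutive expression: Poisson(k_s/k_d) on [0, n_max]."""
    if k_s <= 0 or k_d <= 0:
        raise ModelError("rates must be positive")
    lam = k_s / k_d
    if n_max < lam + 6 * np.sqrt(lam):
        warnings.warn(
            f"n_max={n_max} truncates Poisson(lambda={lam:g}) before "
            "lambda + 6*sqrt(lambda); captured mass < 1 - 1e-6",
            stacklevel=2,
        )
    w = poisson.pmf(np.arange(n_max + 1), lam)
    return DistributionGrid(StateSpace([n_max]), w)
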