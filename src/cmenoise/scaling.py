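"""Rescaled steady-state CME for systems with large molecule numbers.

For molecule numbers far beyond what a full lattice enumeration allows,
the master equation is approximated on a coarse lattice with spacing S
(an integer scale factor, S=1 meaning no scaling): each fixed-change
reaction j moves a coarse point x to x + S*v_j at its original propensity
a_j(x).  This finite-difference construction reduces bit-exactly to the
unscaled generator at S=1, and for the birth-death chain it preserves the
successive-point ratio P(n)/P(n-S) = k_s/(k_d n), so the distribution
still peaks at n = k_s/k_d for every S.

Under sufficiently slow variation of P between neighbouring coarse points,
each coarse point stands for the S^d fine states around it; the
normalization assigns it that aggregated mass.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .network import DistributionGrid, ModelError, ReactionNetwork, StateSpace
from .steady_state import _assemble

__all__ = ["coarse_space", "build_scaled_generator", "normalize_scaled"]


def coarse_space(space: StateSpace, S: int) -> StateSpace:
    """The coarse lattice: multiples of S inside the same box."""
    return StateSpace(space.upper, scale=S)


def build_scaled_generator(
    network: ReactionNetwork, space: StateSpace, S: int
) -> tuple[sp.csc_matrix, StateSpace]:
    """Rate matrix of the rescaled CME on the coarse lattice.

    Jump-kernel reactions are rejected for S>1 (their destinations do not
    live on the coarse lattice).  Returns the matrix and the coarse space.
    """
    if S < 1:
        raise ModelError("scale factor S must be >= 1")
    if S > 1 and any(r.is_jump for r in network.reactions):
        raise ModelError("jump-kernel reactions are not supported with S > 1")
    cspace = coarse_space(space, S)
    return _assemble(network, cspace, S=S), cspace


def normalize_scaled(raw: np.ndarray, space: StateSpace) -> DistributionGrid:
    """Normalize a raw nonnegative coarse-point vector into a distribution.

    The returned grid's ``mass`` is the aggregated probability per coarse
    point (sums to 1); its ``density`` property divides by S^d to give the
    per-fine-state view.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ModelError("raw mass must be nonnegative")
    if raw.sum() <= 0:
        raise ModelError("all-zero raw mass vector")
    return DistributionGrid(space, raw)
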