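"""Extrinsic noise as a convolution with a distribution of shifts.

Whatever is outside the modeled reactions -- other reactions, rate-constant
fluctuation, measurement noise -- mostly shifts the intrinsic-noise-only
distribution.  Pooling many such shifts yields a convolution of the
intrinsic distribution with a shift distribution, taken zero-mean
multivariate normal, plus an optional small background component:

    P_observed = (1 - a) * (P_intrinsic * M_0) + a * B

where ``M_0`` is the normal kernel renormalized on the truncated lattice,
``a`` in [0, 1) is the background weight and ``B`` the background
distribution.  For a sampled representation the same convolution is
realized by adding an independent normal shift to every sample and
appending n*a/(1-a) background draws.

The gamma parameter-mixing route is also provided for the constitutive
birth-death model: drawing y = k_s/k_d from Gamma(alpha, theta) and mixing
the Poisson(y) distributions gives the negative-binomial closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.signal
from scipy.stats import multivariate_normal, nbinom

from .gibbs import SampleSet
from .network import DistributionGrid, ModelError, StateSpace

__all__ = [
    "ExtrinsicNoiseSpec",
    "convolve_grid",
    "shift_samples",
    "gamma_mixed_birth_death",
    "fit_extrinsic_sigma",
    "SigmaFit",
]


def _as_cov(cov, d: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = np.eye(d) * float(cov) ** 2  # scalar = isotropic std dev
    elif cov.ndim == 1:
        cov = np.diag(cov**2)  # vector = per-species std devs
    if cov.shape != (d, d):
        raise ModelError(f"covariance shape {cov.shape} does not match d={d}")
    if not np.allclose(cov, cov.T):
        raise ModelError("covariance must be symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
        raise ModelError("covariance must be positive semidefinite")
    return cov


@dataclass
class ExtrinsicNoiseSpec:
    """Shift-distribution parameters of the extrinsic-noise convolution.

    ``cov`` may be a scalar standard deviation, a per-species vector of
    standard deviations, or a full covariance matrix (molecule units
    squared).  ``background_weight`` is the constant ``a``; ``background``
    the distribution ``B`` (defaults to uniform over the box).  ``modes``
    optionally assigns a different covariance per mode: a list of
    ``(center, cov)`` pairs, states being attributed to the nearest center
    in Euclidean distance.  ``shift`` is an optional deterministic mean
    shift of the kernel (used by the sigma fit).
    """

    cov: object = 0.0
    background_weight: float = 0.0
    background: DistributionGrid | None = None
    modes: Sequence[tuple] | None = None
    shift: object = None

    def covariance(self, d: int) -> np.ndarray:
        return _as_cov(self.cov, d)

    def mean_shift(self, d: int) -> np.ndarray:
        if self.shift is None:
            return np.zeros(d)
        return np.broadcast_to(np.asarray(self.shift, dtype=float), (d,)).copy()


def _gaussian_kernel(cov: np.ndarray, mean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discrete normal kernel on an odd box of integer offsets, normalized
    to total mass 1.  A zero covariance degenerates to the rounded-shift
    delta kernel."""
    d = cov.shape[0]
    sd = np.sqrt(np.diag(cov))
    half = np.maximum(np.ceil(6 * sd + np.abs(mean)).astype(int), 1)
    axes = [np.arange(-h, h + 1) for h in half]
    mesh = np.meshgrid(*axes, indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=-1).astype(float)
    if np.allclose(cov, 0.0):
        k = np.all(offsets == np.rint(mean), axis=-1).astype(float)
        if k.sum() == 0:  # shift beyond the kernel box: widen
            raise ModelError("mean shift outside kernel support")
    else:
        k = multivariate_normal.pdf(offsets, mean=mean, cov=cov, allow_singular=True)
    k = k.reshape([2 * h + 1 for h in half])
    return k / k.sum(), half


def _conv_same(p: np.ndarray, kernel: np.ndarray, method: str) -> np.ndarray:
    return scipy.signal.convolve(p, kernel, mode="same", method=method)


def _corr_same(p: np.ndarray, kernel: np.ndarray, method: str) -> np.ndarray:
    return scipy.signal.correlate(p, kernel, mode="same", method=method)


def _convolve_component(
    p: np.ndarray, cov: np.ndarray, mean: np.ndarray, method: str
) -> np.ndarray:
    """Boundary-renormalized convolution of a (possibly unnormalized)
    grid component with the discrete normal kernel: no mass leaves the
    box, each source state's kernel being renormalized over in-box
    destinations."""
    kernel, _ = _gaussian_kernel(cov, mean)
    z = _corr_same(np.ones_like(p), kernel, method)
    z = np.where(z <= 0, 1.0, z)
    return _conv_same(p / z, kernel, method)


def convolve_grid(
    p: DistributionGrid, spec: ExtrinsicNoiseSpec, method: str = "direct"
) -> DistributionGrid:
    """Apply the extrinsic-noise convolution to a lattice distribution.

    ``method`` selects direct summation or the FFT fast path
    ("direct"/"fft"); both agree to within roundoff.  Mass is conserved
    exactly: the kernel is renormalized per source state over in-box
    destinations.
    """
    a = float(spec.background_weight)
    if not 0.0 <= a < 1.0:
        raise ModelError("background weight a must be in [0, 1)")
    d = p.space.n_species
    grid = p.grid
    mean = spec.mean_shift(d)
    if spec.modes is not None:
        states = p.space.states().reshape(p.space.shape + (d,))
        centers = np.asarray([np.asarray(c, dtype=float) for c, _ in spec.modes])
        dist2 = ((states[..., None, :] - centers) ** 2).sum(axis=-1)
        owner = np.argmin(dist2, axis=-1)
        out = np.zeros_like(grid)
        for k, (_, cov_k) in enumerate(spec.modes):
            part = np.where(owner == k, grid, 0.0)
            if part.sum() > 0:
                out += _convolve_component(part, _as_cov(cov_k, d), mean, method)
    else:
        out = _convolve_component(grid, spec.covariance(d), mean, method)
    out = out.reshape(-1)
    if a > 0:
        b = spec.background
        bmass = (
            np.full(p.space.n_states, 1.0 / p.space.n_states)
            if b is None
            else b.mass
        )
        out = (1 - a) * out + a * bmass
    return DistributionGrid(p.space, out)


def shift_samples(
    samples: SampleSet,
    spec: ExtrinsicNoiseSpec,
    seed: int | None = None,
    space: StateSpace | None = None,
    round_to_lattice: bool = False,
) -> SampleSet:
    """Sample-based counterpart of :func:`convolve_grid`.

    Each sample receives an independent normal shift (per-mode covariance
    if ``spec.modes`` is set); negative components are clipped to zero,
    which biases the result near the boundary (documented trade-off
    against the grid route's kernel renormalization).  Values are
    continuous unless ``round_to_lattice``.  With a background weight
    a > 0, ``round(n a/(1-a))`` extra points drawn from the background
    distribution are appended (``space`` or ``spec.background`` must then
    be given).
    """
    if len(samples) == 0:
        raise ModelError("empty sample set")
    rng = np.random.default_rng(seed)
    x = samples.states.astype(float)
    n, d = x.shape
    mean = spec.mean_shift(d)
    if spec.modes is not None:
        centers = np.asarray([np.asarray(c, dtype=float) for c, _ in spec.modes])
        owner = np.argmin(((x[:, None, :] - centers) ** 2).sum(axis=-1), axis=-1)
        y = x.copy()
        for k, (_, cov_k) in enumerate(spec.modes):
            sel = owner == k
            if sel.any():
                y[sel] += rng.multivariate_normal(
                    mean, _as_cov(cov_k, d), size=int(sel.sum())
                )
    else:
        cov = spec.covariance(d)
        y = x + rng.multivariate_normal(mean, cov, size=n)
    a = float(spec.background_weight)
    if not 0.0 <= a < 1.0:
        raise ModelError("background weight a must be in [0, 1)")
    if a > 0:
        extra = int(round(n * a / (1 - a)))
        if extra > 0:
            if spec.background is not None:
                bg = spec.background.sample_states(extra, rng).astype(float)
            elif space is not None:
                bg = np.column_stack(
                    [rng.integers(0, u + 1, size=extra) for u in space.upper]
                ).astype(float)
            else:
                raise ModelError("background sampling needs a space or background grid")
            y = np.concatenate([y, bg])
    y = np.clip(y, 0.0, None)
    if round_to_lattice:
        y = np.rint(y).astype(int)
    meta = dict(samples.metadata)
    meta.update({"extrinsic_seed": seed, "rounded": round_to_lattice})
    return SampleSet(y, metadata=meta)


def gamma_mixed_birth_death(alpha: float, theta: float, n_max: int) -> DistributionGrid:
    """Constitutive expression with gamma-mixed mean: negative binomial.

    Mixing Poisson(y) over y = k_s/k_d ~ Gamma(shape alpha, scale theta)
    gives P(n) = C(n+alpha-1, n) (theta/(1+theta))^n (1/(1+theta))^alpha,
    renormalized on [0, n_max].  Mean alpha*theta, variance
    alpha*theta*(1+theta).
    """
    if alpha <= 0 or theta <= 0:
        raise ModelError("alpha and theta must be positive")
    w = nbinom.pmf(np.arange(n_max + 1), alpha, 1.0 / (1.0 + theta))
    return DistributionGrid(StateSpace([n_max]), w)


@dataclass
class SigmaFit:
    sigma: float
    shift: float
    residual: float


def fit_extrinsic_sigma(
    p_intrinsic: DistributionGrid,
    p_target: DistributionGrid,
    fit_shift: bool = False,
    sigma_max: float | None = None,
) -> SigmaFit:
    """Least-squares fit of the extrinsic-noise width.

    Minimizes ``sum_states (convolve_grid(P_intrinsic, sigma) - P_target)^2``
    over the scalar standard deviation sigma (and, optionally, a scalar
    mean shift applied uniformly to all species).  Returns the fitted
    values and the residual sum of squares.
    """
    if p_intrinsic.space != p_target.space:
        raise ModelError("distributions must share a state space")
    if np.ptp(p_target.mass) < 1e-15:
        warnings.warn("flat target distribution: sigma is unidentifiable", stacklevel=2)
    if sigma_max is None:
        sigma_max = float(np.max(p_target.space.upper)) / 2.0

    def objective(sigma: float, shift: float) -> float:
        spec = ExtrinsicNoiseSpec(cov=max(sigma, 0.0), shift=shift)
        q = convolve_grid(p_intrinsic, spec)
        return float(np.sum((q.mass - p_target.mass) ** 2))

    if fit_shift:
        d0 = float(p_target.mean().mean() - p_intrinsic.mean().mean())
        s0 = _initial_sigma(p_intrinsic, p_target)
        res = scipy.optimize.minimize(
            lambda v: objective(v[0], v[1]),
            x0=np.array([s0, d0]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-12},
        )
        sigma, shift = float(abs(res.x[0])), float(res.x[1])
        return SigmaFit(sigma, shift, float(res.fun))
    res = scipy.optimize.minimize_scalar(
        lambda s: objective(s, 0.0), bounds=(0.0, sigma_max), method="bounded",
        options={"xatol": 1e-5},
    )
    return SigmaFit(float(res.x), 0.0, float(res.fun))


def _initial_sigma(p: DistributionGrid, q: DistributionGrid) -> float:
    """Moment-matching initial guess for the extrinsic width."""
    v = float(q.std().mean() ** 2 - p.std().mean() ** 2)
    return float(np.sqrt(max(v, 0.25)))
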