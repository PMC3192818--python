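"""Summary statistics, ON/OFF partition rules and the SSD distance.

Two partition rules are used for bimodal circuits: the dominant-species
rule for the toggle switch (a state is ON when the monitored protein
outnumbers the other; mass on the tie diagonal is split evenly by
default) and the valley rule for one-dimensional histograms (border at
the lowest bin between the two most prominent peaks, falling back to the
point of smallest finite-difference slope when the peaks blur into a
shoulder).  Distributions are compared by the sum of squared deviations
(SSD) over states, which is at most 2 (disjoint point masses).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gibbs import SampleSet
from .network import DistributionGrid, ModelError, StateSpace

__all__ = [
    "summarize",
    "on_fraction_dominant",
    "on_fraction_valley",
    "ssd",
    "find_peaks_and_border",
]


def summarize(dist, species: list[str] | None = None) -> pd.DataFrame:
    """Per-species mean and standard deviation.

    Exact moments for a :class:`DistributionGrid`, sample moments
    (population normalization) for a :class:`SampleSet`.
    """
    if isinstance(dist, DistributionGrid):
        mean, sd = dist.mean(), dist.std()
    elif isinstance(dist, SampleSet):
        if len(dist) == 0:
            raise ModelError("empty sample set")
        mean, sd = dist.mean(), dist.std()
    else:
        raise TypeError(f"cannot summarize {type(dist).__name__}")
    if species is None:
        species = [f"s{i}" for i in range(len(mean))]
    return pd.DataFrame({"mean": mean, "sd": sd}, index=species)


def on_fraction_dominant(dist: DistributionGrid, tie_weight: float = 0.5) -> float:
    """Fraction of mass where the first species dominates the second.

    ON = sum_{u>v} P + tie_weight * sum_{u=v} P; with the default
    tie_weight of 0.5 the ON and complementary fractions add to 1 exactly
    and a fully symmetric system scores exactly 0.5.
    """
    if dist.space.n_species != 2:
        raise ModelError("dominant-species rule needs exactly two species")
    u = dist.marginal_values(0)[:, None]
    v = dist.marginal_values(1)[None, :]
    g = dist.grid
    return float(g[u > v].sum() + tie_weight * g[u == v].sum())


def _local_maxima(h: np.ndarray) -> list[tuple[float, int]]:
    """(height, leftmost index) of each local maximum, plateaus merged."""
    peaks = []
    i, n = 0, len(h)
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[j]:
            j += 1
        left = h[i - 1] if i > 0 else -np.inf
        right = h[j + 1] if j + 1 < n else -np.inf
        if h[i] > left and h[j] > right:
            peaks.append((float(h[i]), i))
        i = j + 1
    return peaks


def find_peaks_and_border(h: np.ndarray) -> int:
    """Border bin of the valley rule.

    With two or more local maxima, the two most prominent (largest by
    height) delimit the valley and the border is the lowest bin strictly
    between them.  With a single peak the shoulder rule applies: the
    border is the point of smallest finite-difference magnitude.
    """
    h = np.asarray(h, dtype=float)
    if len(h) < 2:
        raise ModelError("histogram needs at least two bins")
    peaks = sorted(_local_maxima(h), reverse=True)
    if len(peaks) >= 2:
        a, b = sorted((peaks[0][1], peaks[1][1]))
        if b > a + 1:
            return a + 1 + int(np.argmin(h[a + 1 : b]))
        return b
    d = np.abs(np.diff(h))
    return int(np.argmin(d))


def on_fraction_valley(hist) -> tuple[float, int]:
    """ON fraction of a 1-D histogram under the valley rule.

    ON is the high-molecule-number side: all mass strictly above the
    border bin (the border itself counts as OFF).  Returns
    (fraction, border index).
    """
    if isinstance(hist, DistributionGrid):
        if hist.space.n_species != 1:
            raise ModelError("valley rule needs a one-dimensional distribution")
        h = hist.mass
    else:
        h = np.asarray(hist, dtype=float)
        if h.sum() <= 0:
            raise ModelError("empty histogram")
        h = h / h.sum()
    border = find_peaks_and_border(h)
    return float(h[border + 1 :].sum()), border


def _as_mass(obj, space: StateSpace | None) -> tuple[np.ndarray, StateSpace]:
    if isinstance(obj, DistributionGrid):
        return obj.mass, obj.space
    if isinstance(obj, SampleSet):
        if space is None:
            raise ModelError("histogramming a sample set needs a state space")
        return obj.histogram(space).mass, space
    raise TypeError(f"cannot interpret {type(obj).__name__} as a distribution")


def ssd(p, q, space: StateSpace | None = None) -> float:
    """Sum over states of squared probability differences (range [0, 2]).

    Sample sets are histogrammed onto the shared state space first; the
    two inputs must live on the same space.
    """
    if space is None:
        for obj in (p, q):
            if isinstance(obj, DistributionGrid):
                space = obj.space
                break
    pm, ps = _as_mass(p, space)
    qm, qs = _as_mass(q, space)
    if ps != qs:
        raise ModelError("distributions live on different state spaces")
    return float(np.sum((pm - qm) ** 2))
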