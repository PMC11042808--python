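"""Discrete stimulus distributions shared by task generation and observer models.

Stimulus amplitudes live on a finite grid in [0, 1] with marginal
probabilities ``p_m``.  The same object serves three roles: sampling
weights for the first stimulus of a trial, the replacement buffer of the
epsilon-replacement observer, and the prior of the Bayesian observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LABELS = ("uniform", "symmetric", "neg_skewed", "pos_skewed", "bimodal")


@dataclass(frozen=True)
class StimulusDistribution:
    """A discrete probability distribution over stimulus amplitudes.

    Parameters
    ----------
    support
        Strictly increasing stimulus values in [0, 1].
    probs
        Marginal probabilities ``p_m``, nonnegative, summing to 1.
    label
        One of ``uniform | symmetric | neg_skewed | pos_skewed | bimodal``.
    """

    support: np.ndarray
    probs: np.ndarray
    label: str = "uniform"

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-D arrays of equal length")
        if support.size < 2:
            raise ValueError("support needs at least two values")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if support[0] < 0 or support[-1] > 1:
            raise ValueError("support must lie in [0, 1]")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1 (within 1e-12)")
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {_LABELS}")

    @property
    def n(self) -> int:
        return int(self.support.size)

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)

    @property
    def median(self) -> float:
        """Generalized median: smallest support value with CDF >= 1/2."""
        cdf = np.cumsum(self.probs)
        return float(self.support[np.searchsorted(cdf, 0.5)])

    def index_of(self, s: float, tol: float = 1e-9) -> int:
        """Index of ``s`` in the support; raises if ``s`` is off-grid."""
        i = int(np.argmin(np.abs(self.support - s)))
        if abs(self.support[i] - s) > tol:
            raise ValueError(f"stimulus {s} is not on the support grid")
        return i

    def pm(self, s: float) -> float:
        return float(self.probs[self.index_of(s)])

    def cdf_below(self, s: float) -> float:
        """Mass strictly below ``s`` (s on the support)."""
        i = self.index_of(s)
        return float(self.probs[:i].sum())

    def cdf_above(self, s: float) -> float:
        """Mass strictly above ``s`` (s on the support)."""
        i = self.index_of(s)
        return float(self.probs[i + 1:].sum())

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.choice(self.support, size=size, p=self.probs)

    def collision_probability(self) -> float:
        """Probability two independent draws coincide, sum_i p_m(i)^2."""
        return float(np.sum(self.probs ** 2))


def make_distribution(label: str, support=None, skew: float = 2.0,
                      mode_sep: float = 0.3, mode_weight: float = 0.45) -> StimulusDistribution:
    """Build one of the named stimulus distributions on a discrete grid.

    Parameters
    ----------
    label
        ``uniform``: equal mass on every grid point.
        ``symmetric``: triangular mass peaked at the grid center (mean = median).
        ``neg_skewed``: mass increasing with s (long left tail, median > mean).
        ``pos_skewed``: mirror image (median < mean).
        ``bimodal``: two separated modes with a low-probability middle.
    support
        Grid of stimulus values; default 10 evenly spaced points in [0.1, 0.9].
    skew
        Exponent shaping the skewed variants (larger = more skewed).
    mode_sep, mode_weight
        Bimodal geometry: modes sit ``mode_sep`` from the grid center and
        each mode carries roughly ``mode_weight`` of the mass.
    """
    if support is None:
        support = np.linspace(0.1, 0.9, 10)
    support = np.asarray(support, dtype=float)
    n = support.size
    if label == "uniform":
        probs = np.full(n, 1.0 / n)
    elif label == "symmetric":
        center = 0.5 * (support[0] + support[-1])
        half = 0.5 * (support[-1] - support[0])
        probs = 1.0 + (1.0 - np.abs(support - center) / half) * 3.0
    elif label == "neg_skewed":
        rank = np.linspace(0.05, 1.0, n)
        probs = rank ** skew
    elif label == "pos_skewed":
        rank = np.linspace(0.05, 1.0, n)
        probs = rank[::-1] ** skew
    elif label == "bimodal":
        center = 0.5 * (support[0] + support[-1])
        width = max(0.08, (support[-1] - support[0]) / (n - 1))
        left = np.exp(-0.5 * ((support - (center - mode_sep)) / width) ** 2)
        right = np.exp(-0.5 * ((support - (center + mode_sep)) / width) ** 2)
        probs = mode_weight * left / left.sum() + mode_weight * right / right.sum()
        probs = probs + (1.0 - probs.sum()) / n
    else:
        raise ValueError(f"unknown label {label!r}; expected one of {_LABELS}")
    probs = np.clip(probs, 1e-12, None)
    probs = probs / probs.sum()
    return StimulusDistribution(support=support, probs=probs, label=label)
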