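"""Probability distributions over integer cable lengths.

A :class:`LengthDistribution` is a probability mass function on subunit
counts ``0..l_max`` together with a provenance tag saying how it was obtained
(analytic recursion, closed form, master-equation oracle, or empirical
counts).  Distances between distributions are measured in total variation,
optionally after aggregating neighbouring lengths into fixed-width bins —
necessary when comparing a finite empirical sample against a smooth reference
on a support thousands of subunits wide, where single-subunit total variation
has a large sampling floor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .params import SUBUNITS_PER_MICRON

_NORMALIZATION_TOL = 1e-9


class Provenance(enum.Enum):
    ANALYTIC_RECURSION = "analytic_recursion"
    CLOSED_FORM = "closed_form"
    ORACLE = "oracle"
    EMPIRICAL = "empirical"


class Moments(NamedTuple):
    mean: float
    variance: float
    cv2: float


@dataclass(frozen=True)
class LengthDistribution:
    """Probability mass over integer cable lengths ``0..l_max``.

    ``p[l]`` is the probability of length ``l`` subunits.  ``p_on``/``p_off``
    optionally carry the formin-state-resolved split (summing to ``p``).
    """

    p: np.ndarray
    provenance: Provenance
    p_on: Optional[np.ndarray] = field(default=None, repr=False)
    p_off: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("p must be a non-empty 1-d array")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _NORMALIZATION_TOL:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_weights(
        cls,
        weights: np.ndarray,
        provenance: Provenance,
        p_on: Optional[np.ndarray] = None,
        p_off: Optional[np.ndarray] = None,
    ) -> "LengthDistribution":
        """Normalize non-negative weights into a distribution."""
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if not total > 0:
            raise ValueError("weights must have positive total mass")
        scale = 1.0 / total
        return cls(
            weights * scale,
            provenance,
            None if p_on is None else np.asarray(p_on, float) * scale,
            None if p_off is None else np.asarray(p_off, float) * scale,
        )

    @classmethod
    def from_samples(cls, lengths: np.ndarray) -> "LengthDistribution":
        """Empirical distribution from integer length samples (exact, by counts)."""
        lengths = np.asarray(lengths)
        if lengths.size == 0:
            raise ValueError("need at least one sample")
        if np.any(lengths < 0):
            raise ValueError("lengths must be non-negative")
        counts = np.bincount(lengths.astype(np.int64).ravel())
        return cls(counts / counts.sum(), Provenance.EMPIRICAL)

    # -- accessors -----------------------------------------------------------

    @property
    def support(self) -> np.ndarray:
        """Integer lengths 0..l_max."""
        return np.arange(self.p.size)

    @property
    def l_max(self) -> int:
        return self.p.size - 1

    def mean(self) -> float:
        return float(np.dot(self.support, self.p))

    def variance(self) -> float:
        m = self.mean()
        return float(np.dot(self.support.astype(float) ** 2, self.p) - m * m)

    def cv2(self) -> float:
        """Squared coefficient of variation (variance/mean^2); NaN at mean 0."""
        m = self.mean()
        if m == 0:
            return float("nan")
        return self.variance() / (m * m)

    def moments(self) -> Moments:
        return Moments(self.mean(), self.variance(), self.cv2())

    def tail_mass(self, l_from: int) -> float:
        """Probability mass at lengths >= ``l_from``."""
        if l_from > self.l_max:
            return 0.0
        return float(self.p[max(l_from, 0):].sum())

    # -- export --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_subunits": self.support,
                "length_um": self.support / SUBUNITS_PER_MICRON,
                "probability": self.p,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def distribution_moments(dist: LengthDistribution) -> Moments:
    """Mean (subunits), variance (subunits^2) and CV^2 of a distribution."""
    return dist.moments()


def _padded(a: np.ndarray, n: int) -> np.ndarray:
    if a.size == n:
        return a
    out = np.zeros(n)
    out[: a.size] = a
    return out


def rebin(p: np.ndarray, bin_width: int) -> np.ndarray:
    """Aggregate a pmf on 0..l_max into contiguous bins of ``bin_width`` lengths."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if bin_width == 1:
        return np.asarray(p, float)
    p = np.asarray(p, float)
    n_bins = -(-p.size // bin_width)
    return _padded(p, n_bins * bin_width).reshape(n_bins, bin_width).sum(axis=1)


def tv_distance(
    a: LengthDistribution | np.ndarray,
    b: LengthDistribution | np.ndarray,
    bin_width: int = 1,
) -> float:
    """Total-variation distance, ``0.5 * sum |p_a - p_b|``, in [0, 1].

    With ``bin_width > 1`` both pmfs are first aggregated into bins of that
    many subunits.  Comparisons involving empirical distributions should use
    a bin width of roughly half the distribution's standard deviation so that
    the finite-sample floor of the statistic stays well below the tolerances
    used in agreement checks.
    """
    pa = a.p if isinstance(a, LengthDistribution) else np.asarray(a, float)
    pb = b.p if isinstance(b, LengthDistribution) else np.asarray(b, float)
    n = max(pa.size, pb.size)
    pa, pb = _padded(pa, n), _padded(pb, n)
    if bin_width > 1:
        pa, pb = rebin(pa, bin_width), rebin(pb, bin_width)
    return float(min(0.5 * np.abs(pa - pb).sum(), 1.0))
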