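"""Gray-level histograms and the classic / restricted-range multi-level Otsu objectives.

The classic Otsu criterion picks thresholds that maximize the between-class
variance of the gray-level histogram.  The restricted-range variant first cuts
the histogram at a gray level ``Th`` and applies the criterion only to the
conditional distribution of levels above ``Th``, so a dominant dark background
cannot drag the thresholds left.  Exhaustive solvers are provided as
correctness oracles for the metaheuristic search; they enumerate every
admissible threshold tuple and are intended for reduced level counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmptyRangeError",
    "NoSeparationError",
    "GrayHistogram",
    "RestrictedHistogram",
    "ObjectiveValue",
    "compute_histogram",
    "restrict_histogram",
    "between_class_variance_single",
    "multi_otsu_objective",
    "exhaustive_otsu_single",
    "exhaustive_otsu_multi",
]


class EmptyRangeError(ValueError):
    """No pixels fall in the restricted gray range (Th+1 .. L-1)."""


class NoSeparationError(ValueError):
    """The histogram occupies fewer than two gray levels; no threshold separates it."""


@dataclass(frozen=True)
class GrayHistogram:
    """Per-level pixel counts of an 8-bit (or reduced-depth) grayscale image.

    counts[i] is the number of pixels at gray level i; ``total`` is M*N.
    Probabilities are exact integer counts divided once at the end.
    """

    counts: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.shape[0] != self.levels:
            raise ValueError(f"counts must be a 1-D array of length {self.levels}")
        if (counts < 0).any():
            raise ValueError("negative histogram counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.total
        if total == 0:
            raise ValueError("empty histogram has no probabilities")
        return self.counts / total

    def occupied_levels(self) -> np.ndarray:
        return np.flatnonzero(self.counts)

    def to_csv(self, path) -> None:
        """Write a two-column CSV (level, count) covering all levels."""
        arr = np.column_stack([np.arange(self.levels), self.counts])
        np.savetxt(path, arr, fmt="%d", delimiter=",", header="level,count", comments="")

    @classmethod
    def from_csv(cls, path, levels: int = 256) -> "GrayHistogram":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
        counts = np.zeros(levels, dtype=np.int64)
        counts[arr[:, 0]] = arr[:, 1]
        return cls(counts=counts, levels=levels)

    @classmethod
    def from_counts(cls, mapping: dict, levels: int = 256) -> "GrayHistogram":
        counts = np.zeros(levels, dtype=np.int64)
        for level, count in mapping.items():
            counts[int(level)] = int(count)
        return cls(counts=counts, levels=levels)


@dataclass(frozen=True)
class RestrictedHistogram:
    """Histogram conditioned on gray levels above a first cut ``th``.

    ``p_r[i]`` = n_i / n_r for i in [th+1, L-1] (zero below), where n_r is the
    pixel count above the cut.  ``p_l`` is the mirror conditional distribution
    on [0, th], retained for completeness.
    """

    th: int
    counts: np.ndarray
    levels: int

    @property
    def n_l(self) -> int:
        return int(self.counts[: self.th + 1].sum())

    @property
    def n_r(self) -> int:
        return int(self.counts[self.th + 1 :].sum())

    @property
    def p_r(self) -> np.ndarray:
        p = np.zeros(self.levels, dtype=float)
        n_r = self.n_r
        p[self.th + 1 :] = self.counts[self.th + 1 :] / n_r
        return p

    @property
    def p_l(self) -> np.ndarray:
        p = np.zeros(self.levels, dtype=float)
        n_l = self.n_l
        if n_l > 0:
            p[: self.th + 1] = self.counts[: self.th + 1] / n_l
        return p

    @property
    def range_mean(self) -> float:
        """Mean gray level of the conditional distribution above the cut."""
        idx = np.arange(self.levels)
        return float((idx * self.p_r).sum())


@dataclass(frozen=True)
class ObjectiveValue:
    """Between-class variance and its per-class decomposition."""

    value: float
    weights: np.ndarray
    means: np.ndarray  # NaN where the class is empty
    grand_mean: float


def compute_histogram(image, levels: int = 256) -> GrayHistogram:
    """Count pixels per gray level.

    ``image`` is any 2-D integer array with values in [0, levels-1].
    """
    pixels = np.asarray(image)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError("image must contain integer gray levels")
    if pixels.min() < 0 or pixels.max() > levels - 1:
        raise ValueError(f"gray levels must lie in [0, {levels - 1}]")
    counts = np.bincount(pixels.ravel(), minlength=levels).astype(np.int64)
    return GrayHistogram(counts=counts, levels=levels)


def restrict_histogram(hist: GrayHistogram, th: int) -> RestrictedHistogram:
    """Condition ``hist`` on gray levels above ``th``.

    Raises :class:`EmptyRangeError` if no pixels lie above the cut; callers
    (the segmentation pipeline) must handle that by lowering ``th``.
    ``th = -1`` places the cut below gray 0, i.e. no restriction at all.
    """
    if not -1 <= th <= hist.levels - 2:
        raise ValueError(f"th must lie in [-1, {hist.levels - 2}]")
    n_r = int(hist.counts[th + 1 :].sum())
    if n_r == 0:
        raise EmptyRangeError(f"no pixels above gray level {th}")
    return RestrictedHistogram(th=th, counts=hist.counts, levels=hist.levels)


def between_class_variance_single(hist: GrayHistogram, k: int) -> float:
    """Between-class variance of the two-class split at threshold ``k``.

    Classes are [0, k] and [k+1, L-1].  Uses the cumulative form
    sigma_B^2(k) = (mG*P1 - m)^2 / (P1*(1-P1)); a degenerate partition
    (P1 in {0, 1}) contributes no separation and returns 0.
    """
    if not 0 <= k <= hist.levels - 2:
        raise ValueError(f"k must lie in [0, {hist.levels - 2}]")
    p = hist.probabilities
    idx = np.arange(hist.levels)
    p1 = float(p[: k + 1].sum())
    if p1 <= 0.0 or p1 >= 1.0:
        return 0.0
    m_k = float((idx[: k + 1] * p[: k + 1]).sum())
    m_g = float((idx * p).sum())
    return (m_g * p1 - m_k) ** 2 / (p1 * (1.0 - p1))


def _prefix_sums(p: np.ndarray):
    """Inclusive prefix sums of p and i*p, padded so sum over (a, b] is
    cp[b+1]-cp[a+1] with gray levels shifted by one."""
    idx = np.arange(p.shape[0])
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cq = np.concatenate([[0.0], np.cumsum(idx * p)])
    return cp, cq


def multi_otsu_objective(
    rhist: RestrictedHistogram, thresholds, full: bool = False
):
    """Between-class variance of the 5-class (generally q+1-class) partition.

    ``thresholds`` is a non-decreasing sequence of gray levels in
    [th, L-1]; class c covers gray levels (t_{c-1}, t_c] with the implicit
    outer edges th and L-1.  Empty classes contribute zero.  Returns the
    objective value, or an :class:`ObjectiveValue` when ``full`` is true.
    """
    t = np.asarray(thresholds, dtype=np.int64)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("thresholds must be a 1-D sequence")
    if (np.diff(t) < 0).any():
        raise ValueError("thresholds must be sorted non-decreasing")
    if t.min() < rhist.th or t.max() > rhist.levels - 1:
        raise ValueError(f"thresholds must lie in [{rhist.th}, {rhist.levels - 1}]")

    p = rhist.p_r
    cp, cq = _prefix_sums(p)
    edges = np.concatenate([[rhist.th], t, [rhist.levels - 1]])
    w = cp[edges[1:] + 1] - cp[edges[:-1] + 1]
    s = cq[edges[1:] + 1] - cq[edges[:-1] + 1]
    mu = rhist.range_mean
    nonempty = w > 0
    means = np.full(w.shape, np.nan)
    means[nonempty] = s[nonempty] / w[nonempty]
    value = float((w[nonempty] * (means[nonempty] - mu) ** 2).sum())
    if full:
        return ObjectiveValue(value=value, weights=w, means=means, grand_mean=mu)
    return value


def exhaustive_otsu_single(hist: GrayHistogram):
    """Globally optimal single Otsu threshold by scanning every k.

    Returns ``(k_star, value)``; ties break to the smallest k.  Raises
    :class:`NoSeparationError` when fewer than two levels are occupied.
    """
    if hist.occupied_levels().size < 2:
        raise NoSeparationError("histogram occupies fewer than two gray levels")
    p = hist.probabilities
    idx = np.arange(hist.levels)
    cp = np.cumsum(p)[:-1]  # P1(k) for k = 0 .. L-2
    cm = np.cumsum(idx * p)[:-1]
    m_g = float((idx * p).sum())
    sigma = np.zeros(hist.levels - 1)
    interior = (cp > 0.0) & (cp < 1.0)
    sigma[interior] = (m_g * cp[interior] - cm[interior]) ** 2 / (
        cp[interior] * (1.0 - cp[interior])
    )
    k_star = int(np.argmax(sigma))
    return k_star, float(sigma[k_star])


def exhaustive_otsu_multi(
    rhist: RestrictedHistogram, q: int, max_combinations: int = 2_000_000
):
    """Globally optimal q-threshold tuple by full enumeration.

    Enumerates strictly increasing tuples th+1 <= t_1 < ... < t_q <= L-1 in
    lexicographic order and returns ``(thresholds, value)`` with the
    smallest-lexicographic maximizer.  Intended for reduced level counts;
    refuses when the combination count exceeds ``max_combinations``.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    lo, hi = rhist.th + 1, rhist.levels - 1
    n = hi - lo + 1
    if n < q:
        raise ValueError("restricted range narrower than the threshold count")
    from math import comb

    n_comb = comb(n, q)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} combinations exceed the cap {max_combinations}; "
            "reduce the level count or raise the cap"
        )

    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(lo, hi + 1), q)),
        dtype=np.int64,
        count=n_comb * q,
    ).reshape(n_comb, q)

    p = rhist.p_r
    cp, cq = _prefix_sums(p)
    edges = np.concatenate(
        [np.full((n_comb, 1), rhist.th), combos, np.full((n_comb, 1), hi)], axis=1
    )
    w = cp[edges[:, 1:] + 1] - cp[edges[:, :-1] + 1]
    s = cq[edges[:, 1:] + 1] - cq[edges[:, :-1] + 1]
    mu = rhist.range_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(w > 0, s / np.where(w > 0, w, 1.0), mu)
    values = ((w * (means - mu) ** 2).sum(axis=1))
    best = int(np.argmax(values))  # argmax returns the first = lexicographic smallest
    return tuple(int(v) for v in combos[best]), float(values[best])
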