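"""Segmentation-quality metrics and comparison machinery.

Implements PSNR, a whole-image SSIM from global moments, a locally averaged
SSIM-form feature-similarity index (``fsim_paper`` — the formula follows the
published form, which is a mean of local SSIM-style terms rather than the
phase-congruency FSIM of the wider literature), a +-1 per-pixel detail
retention score, reconstruction of the region-valued image from a threshold
set, competition-rank aggregation of metric tables, and the exact one-sided
Wilcoxon signed-rank test by full sign enumeration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricConstants",
    "DetailScore",
    "ComparisonTable",
    "reconstruct_segmented_image",
    "psnr",
    "ssim_global",
    "fsim_paper",
    "detail_score",
    "rank_table",
    "wilcoxon_exact_one_sided",
]


@dataclass(frozen=True)
class MetricConstants:
    """Peak intensity, SSIM stability constants and local window size.

    ``c1 = (k1*max_i)**2`` and ``c2 = (k2*max_i)**2`` with the universal
    k1 = 0.01, k2 = 0.03 defaults; ``window`` is the side of the uniform
    local window used by :func:`fsim_paper`.
    """

    max_i: float = 255.0
    k1: float = 0.01
    k2: float = 0.03
    window: int = 8

    def __post_init__(self) -> None:
        if self.max_i <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("max_i, k1, k2 must be positive")
        if self.window < 2:
            raise ValueError("window must be at least 2")

    @property
    def c1(self) -> float:
        return (self.k1 * self.max_i) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.max_i) ** 2


@dataclass(frozen=True)
class DetailScore:
    """Signed per-pixel agreement tally over a region of length ``length``."""

    total: int
    length: int
    verdicts: np.ndarray


@dataclass
class ComparisonTable:
    """Per-group ranks and per-algorithm average ranks."""

    ranks: pd.DataFrame  # indexed by (group, algorithm), one column per metric
    average_ranks: pd.DataFrame  # indexed by algorithm, one column per metric


def reconstruct_segmented_image(image, thresholds, th: int, levels: int = 256) -> np.ndarray:
    """Replace each pixel by the rounded mean gray of its threshold class.

    Classes follow the pipeline convention: [0, th], (th, t_1], ...,
    (t_q, levels-1].  Classes with no pixels are never queried.
    """
    pixels = np.asarray(image)
    edges = np.array([th, *np.sort(np.asarray(thresholds, dtype=np.int64))])
    labels = np.searchsorted(edges, pixels, side="left")
    out = np.empty_like(pixels)
    for c in range(edges.size + 1):
        sel = labels == c
        if sel.any():
            out[sel] = int(np.round(pixels[sel].mean()))
    return out


def _check_shapes(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def psnr(reference, test, max_i: float = 255.0) -> float:
    """Peak signal-to-noise ratio in decibels; +inf for identical images."""
    x, y = _check_shapes(reference, test)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_i**2 / mse)


def ssim_global(x, y, constants: MetricConstants = MetricConstants()) -> float:
    """Single SSIM value from whole-image means, variances and covariance."""
    x, y = _check_shapes(x, y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    c1, c2 = constants.c1, constants.c2
    return float(
        ((2.0 * mx * my + c1) * (2.0 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def _box_sums(a: np.ndarray, w: int) -> np.ndarray:
    """Sums over every w-by-w window (stride 1, valid positions) via integral image."""
    s = np.cumsum(np.cumsum(a, axis=0), axis=1)
    s = np.pad(s, ((1, 0), (1, 0)))
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def fsim_paper(x, y, constants: MetricConstants = MetricConstants()) -> float:
    """Mean of local SSIM-form terms over all w-by-w windows (stride 1).

    At each window position the luminance and structure factors are computed
    from the local means, variances and cross covariance; the index is the
    average over all window positions.
    """
    x, y = _check_shapes(x, y)
    w = constants.window
    if x.shape[0] < w or x.shape[1] < w:
        raise ValueError(f"image smaller than the {w}x{w} window")
    n = w * w
    mx = _box_sums(x, w) / n
    my = _box_sums(y, w) / n
    vx = _box_sums(x * x, w) / n - mx**2
    vy = _box_sums(y * y, w) / n - my**2
    cov = _box_sums(x * y, w) / n - mx * my
    c1, c2 = constants.c1, constants.c2
    terms = ((2.0 * mx * my + c1) * (2.0 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(terms.mean())


def detail_score(original_region, processed_region, tol: float = 50.0) -> DetailScore:
    """+-1 per-pixel agreement tally: +1 when |difference| <= tol (inclusive)."""
    a = np.asarray(original_region, dtype=float).ravel()
    b = np.asarray(processed_region, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("regions must have equal length")
    verdicts = np.where(np.abs(a - b) <= tol, 1, -1)
    return DetailScore(total=int(verdicts.sum()), length=a.size, verdicts=verdicts)


def rank_table(
    values: pd.DataFrame, metrics=("psnr", "fsim", "ssim"), ties: str = "average"
) -> ComparisonTable:
    """Per-group ranks (1 = largest metric) and per-algorithm averages.

    ``values`` is a long table with columns ``group``, ``algorithm`` and one
    column per metric; it must be rectangular (every algorithm present in
    every group) with no missing cells.  Tied values share the midrank by
    default (``ties="average"``), which is the convention the published
    average rankings follow; ``ties="min"`` gives competition ranks.
    """
    metrics = [m for m in metrics if m in values.columns]
    required = ["group", "algorithm", *metrics]
    missing = [c for c in required if c not in values.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if values[required].isna().any().any():
        raise ValueError("metric table has missing cells")
    counts = values.groupby("group")["algorithm"].nunique()
    if counts.nunique() != 1:
        raise ValueError("metric table is not rectangular across groups")

    df = values.set_index(["group", "algorithm"])[metrics]
    ranks = df.groupby(level="group").rank(ascending=False, method=ties)
    average = ranks.groupby(level="algorithm").mean()
    # keep the input's algorithm order
    order = values["algorithm"].drop_duplicates().tolist()
    average = average.loc[order]
    return ComparisonTable(ranks=ranks, average_ranks=average)


def wilcoxon_exact_one_sided(diffs, alternative: str = "greater") -> float:
    """Exact signed-rank p-value by enumerating all 2^n sign assignments.

    Zero differences are dropped with a warning.  Absolute differences are
    midranked; W+ is the rank sum of the positive differences and the
    one-sided p-value is P(W >= W+) (or P(W <= W+) for ``"less"``) under the
    null that each sign is independently +-1 with probability one half.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("diffs must be a nonempty 1-D sequence")
    nonzero = d != 0.0
    if not nonzero.any():
        raise ValueError("all differences are zero")
    if not nonzero.all():
        warnings.warn("dropping zero differences", stacklevel=2)
        d = d[nonzero]
    n = d.size
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    sums = signs @ ranks
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(sums >= w_plus - eps))
    if alternative == "less":
        return float(np.mean(sums <= w_plus + eps))
    raise ValueError("alternative must be 'greater' or 'less'")
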