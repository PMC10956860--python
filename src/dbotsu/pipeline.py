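"""DBO-Otsu segmentation pipeline for tapping-panel images.

The pipeline restricts the histogram to gray levels above a first cut ``Th``
(the latex / tapping-cut region of interest lives in roughly 150-255 against
a dominant dark background), searches the four-threshold restricted Otsu
objective with the Dung Beetle Optimizer, and derives scar and latex masks
from the optimized thresholds.  A level-dependent strategy handles severe
dryness: when the latex mask is not curvilinear the image is treated as
high-severity and the latex threshold falls back to the brightest occupied
gray level, which isolates sparse latex that no longer forms a histogram
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

from .dbo import DBOParams, run_dbo
from .histogram import (
    EmptyRangeError,
    GrayHistogram,
    RestrictedHistogram,
    _prefix_sums,
    compute_histogram,
    restrict_histogram,
)

__all__ = [
    "PipelineConfig",
    "SegmentationResult",
    "fitness_from_position",
    "segment_multithreshold",
    "assess_curvilinearity",
    "fallback_latex_threshold",
    "segment_tpd",
]


@dataclass
class PipelineConfig:
    """Parameters of the DBO-Otsu segmentation pipeline.

    ``th`` is the first cut separating the dark background from the region of
    interest (default 150).  ``scar_role`` selects which optimized threshold
    bounds the scar class from below: ``"first"`` (default) uses the smallest
    threshold j*, so the scar mask is (j*, m*]; ``"third"`` uses the
    second-largest threshold l*, giving (l*, m*].  The first reading keeps the
    whole bright-band gray range in the scar class even when the optimizer
    spends its middle thresholds subdividing that range, and matches reported
    scar thresholds that hug the lower edge of the restricted range.
    ``e_min`` is the elongation ratio above which the largest latex component
    counts as curvilinear; ``fallback_tol`` widens the fallback latex mask to
    levels >= g_max - fallback_tol.
    """

    th: int = 150
    q: int = 4
    levels: int = 256
    e_min: float = 3.0
    min_component_size: int = 50
    scar_role: str = "first"
    assess_target: str = "latex"  # which mask the morphological assessment inspects
    fallback_tol: int = 0
    n: int = 60
    t_max: int = 200
    seed: int | None = None
    dbo_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1 <= self.th <= self.levels - 2:  # -1 means no restriction
            raise ValueError(f"th must lie in [-1, {self.levels - 2}]")
        if self.e_min <= 1.0:
            raise ValueError("e_min must exceed 1")
        if self.scar_role not in ("first", "third"):
            raise ValueError("scar_role must be 'first' or 'third'")
        if self.assess_target not in ("latex", "scar"):
            raise ValueError("assess_target must be 'latex' or 'scar'")

    def dbo_params(self) -> DBOParams:
        kwargs = dict(
            dim=self.q,
            lb=self.th + 1,
            ub=float(self.levels),
            n=self.n,
            t_max=self.t_max,
            seed=self.seed,
        )
        kwargs.update(self.dbo_overrides)
        return DBOParams(**kwargs)


@dataclass
class SegmentationResult:
    """Thresholds, per-pixel class labels and the scar / latex masks."""

    thresholds: tuple  # (j*, k*, l*, m*), sorted
    scar_threshold: int
    latex_threshold: int
    class_map: np.ndarray  # 0 = below-Th background, 1..q+1 = restricted classes
    scar_mask: np.ndarray
    latex_mask: np.ndarray
    used_fallback: bool
    fitness: float  # minimized fitness = -J at the returned thresholds


def coerce_position(position, th: int, levels: int = 256) -> tuple:
    """Map a continuous optimizer position to an ordered integer threshold tuple.

    Each coordinate is floored, clamped into [th+1, levels-1], then the tuple
    is sorted ascending.  Duplicates are allowed (empty classes score zero).
    """
    t = np.floor(np.asarray(position, dtype=float)).astype(np.int64)
    t = np.clip(t, th + 1, levels - 1)
    t.sort()
    return tuple(int(v) for v in t)


def fitness_from_position(position, rhist: RestrictedHistogram) -> float:
    """Fitness (to minimize) of a continuous position: the negated objective."""
    from .histogram import multi_otsu_objective

    t = coerce_position(position, rhist.th, rhist.levels)
    return -multi_otsu_objective(rhist, t)


def _make_fast_fitness(rhist: RestrictedHistogram):
    """Closure evaluating the negated objective via precomputed prefix sums.

    Numerically identical to :func:`fitness_from_position` (same prefix-sum
    arithmetic) but avoids rebuilding the cumulative arrays per call.
    """
    cp, cq = _prefix_sums(rhist.p_r)
    mu = rhist.range_mean
    th, top = rhist.th, rhist.levels - 1

    def fitness(position) -> float:
        t = np.floor(np.asarray(position, dtype=float)).astype(np.int64)
        np.clip(t, th + 1, top, out=t)
        t.sort()
        j = 0.0
        a = th
        for b in (*t, top):
            w = cp[b + 1] - cp[a + 1]
            if w > 0.0:
                m = (cq[b + 1] - cq[a + 1]) / w
                j += w * (m - mu) ** 2
            a = b
        return -j

    return fitness


def segment_multithreshold(image, config: PipelineConfig) -> SegmentationResult:
    """Initial multi-threshold segmentation: DBO search over the restricted objective.

    The latex threshold is the largest optimized threshold m*; the scar mask
    covers the gray range between the scar threshold (per ``config.scar_role``)
    and m*.  Raises :class:`EmptyRangeError` when no pixels lie above ``th``
    (lower ``th`` in that case).
    """
    pixels = np.asarray(image)
    hist = compute_histogram(pixels, levels=config.levels)
    rhist = restrict_histogram(hist, config.th)

    result = run_dbo(_make_fast_fitness(rhist), config.dbo_params())
    thresholds = coerce_position(result.best_x, config.th, config.levels)

    m_star = thresholds[-1]
    scar_low = thresholds[0] if config.scar_role == "first" else thresholds[-2]

    edges = np.array([config.th, *thresholds], dtype=np.int64)
    class_map = np.searchsorted(edges, pixels, side="left").astype(np.uint8)

    latex_mask = pixels > m_star
    scar_mask = (pixels > scar_low) & (pixels <= m_star)
    return SegmentationResult(
        thresholds=thresholds,
        scar_threshold=int(scar_low),
        latex_threshold=int(m_star),
        class_map=class_map,
        scar_mask=scar_mask,
        latex_mask=latex_mask,
        used_fallback=False,
        fitness=float(result.best_f),
    )


def assess_curvilinearity(mask, config: PipelineConfig) -> bool:
    """True when the largest connected component of ``mask`` is elongated.

    Takes the largest 8-connected component with area >= the configured
    minimum, fits its second-moment ellipse, and compares the major/minor
    axis ratio with ``e_min``.  Empty or undersized masks are not
    curvilinear; a degenerate (zero-minor-axis) component counts as
    curvilinear, being a perfect line.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return False
    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    if largest.area < config.min_component_size:
        return False
    minor = largest.axis_minor_length
    if minor == 0.0:
        return True
    return largest.axis_major_length / minor >= config.e_min


def fallback_latex_threshold(hist: GrayHistogram) -> int:
    """Brightest occupied gray level — the high-severity latex threshold."""
    occupied = hist.occupied_levels()
    if occupied.size == 0:
        raise ValueError("empty histogram")
    return int(occupied[-1])


def segment_tpd(image, config: PipelineConfig) -> SegmentationResult:
    """Full level-dependent segmentation.

    Runs the multi-threshold stage, then a morphological assessment of the
    latex mask (configurable to the scar mask).  A curvilinear mask is kept
    as-is (low-severity path); otherwise the latex threshold is replaced by
    the brightest occupied gray level (high-severity path) and
    ``used_fallback`` is set.  The scar mask is never altered by the
    fallback.
    """
    pixels = np.asarray(image)
    result = segment_multithreshold(pixels, config)
    target = result.latex_mask if config.assess_target == "latex" else result.scar_mask
    if assess_curvilinearity(target, config):
        return result

    hist = compute_histogram(pixels, levels=config.levels)
    g_max = fallback_latex_threshold(hist)
    cutoff = max(g_max - config.fallback_tol, config.th + 1)
    latex_mask = pixels >= cutoff
    # keep masks disjoint: latex claims its pixels back from the scar class
    scar_mask = result.scar_mask & ~latex_mask
    return replace(
        result,
        latex_threshold=int(g_max),
        latex_mask=latex_mask,
        scar_mask=scar_mask,
        used_fallback=True,
    )
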