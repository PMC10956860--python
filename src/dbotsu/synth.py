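"""Synthetic tapping-panel images with ground-truth scar and latex masks.

Real panels are dominated by dark bark (gray around 60) with a bright
curvilinear tapping-cut band and, along it, even brighter latex.  The
generator reproduces that structure with exact ground truth: geometry is
fixed first (band and latex masks), then gray noise is painted, so the masks
match the painted pixels exactly.  The latex deposit is a contiguous run
along the cut (latex flows along the incision), whose angular length is
solved by bisection so the realized latex-to-cut area ratio hits a requested
target.  A sprinkling of bright-bark speckle in the low 150s--160s emulates
the sheen real bark shows above the region-of-interest cut, which is what
anchors the lowest optimized threshold just below the scar gray range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histogram import GrayHistogram

__all__ = ["PanelSpec", "SyntheticPanel", "generate_panel", "generate_histogram_fixture"]


@dataclass
class PanelSpec:
    """Geometry, gray statistics and target area ratio of a synthetic panel.

    The tapping cut is a circular arc of the given ``radius`` spanning
    ``span_deg`` degrees with a band ``width`` pixels across; latex is a thin
    streak (``latex_width`` pixels) along the band centerline covering a
    contiguous angular sub-run sized to the target ratio ``target_lambda``.
    Bright-bark speckle occupies ``bark_fraction`` of the off-band pixels
    with grays in ``bark_range``; the range is kept narrow so the speckle
    forms a coherent gray cluster below the scar band's range.
    """

    shape: tuple = (200, 200)
    bg_mean: float = 60.0
    bg_sd: float = 15.0
    bark_fraction: float = 0.06
    bark_range: tuple = (156, 162)
    radius: float = 170.0
    span_deg: float = 64.0
    width: float = 8.0
    scar_mean: float = 180.0
    scar_sd: float = 8.0
    latex_mean: float = 245.0
    latex_sd: float = 4.0
    latex_width: float = 6.0
    target_lambda: float = 0.40
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target_lambda <= 0:
            raise ValueError("target_lambda must be positive")
        if self.width <= 0 or self.radius <= 0 or self.span_deg <= 0:
            raise ValueError("arc geometry must be positive")


@dataclass
class SyntheticPanel:
    image: np.ndarray  # uint8 grayscale
    scar_mask: np.ndarray  # bool, tapping-cut band minus latex
    latex_mask: np.ndarray  # bool
    lam: float  # realized latex/scar area ratio


def _arc_fields(spec: PanelSpec):
    """Distance-to-center and signed angle-from-vertical for every pixel."""
    h, w = spec.shape
    span = np.deg2rad(spec.span_deg)
    # arc midpoint sits at (0.42*H, W/2) with the center straight below it
    my, mx = 0.42 * h, w / 2.0
    cy, cx = my + spec.radius, mx
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - cy, xx - cx)
    phi = np.arctan2(xx - cx, cy - yy)  # 0 points up toward the arc midpoint
    return dist, phi, span


def generate_panel(spec: PanelSpec) -> SyntheticPanel:
    """Render a panel image with exact ground-truth masks.

    Deterministic given ``spec.seed``.  Raises when the requested ratio is
    geometrically infeasible (the latex run would consume the whole cut).
    """
    rng = np.random.default_rng(spec.seed)
    dist, phi, span = _arc_fields(spec)
    radial_band = np.abs(dist - spec.radius) <= spec.width / 2.0
    radial_latex = np.abs(dist - spec.radius) <= spec.latex_width / 2.0
    band = radial_band & (np.abs(phi) <= span / 2.0)
    n_band = int(band.sum())
    if n_band == 0:
        raise ValueError("scar band is empty; enlarge the image or the arc")

    # center of the latex run along the cut (geometry drawn before noise)
    phi0 = rng.uniform(-span / 2.0, span / 2.0)

    def latex_at(length: float) -> np.ndarray:
        lo = max(phi0 - length / 2.0, -span / 2.0)
        hi = min(phi0 + length / 2.0, span / 2.0)
        return radial_latex & (phi >= lo) & (phi <= hi)

    def ratio_at(length: float) -> float:
        latex = latex_at(length)
        s2 = int((band & ~latex).sum())
        if s2 == 0:
            return np.inf
        return int(latex.sum()) / s2

    max_len = 0.95 * span  # keep some cut visible
    if ratio_at(max_len) < spec.target_lambda:
        raise ValueError(
            f"target ratio {spec.target_lambda} infeasible for this geometry"
        )
    lo, hi = 0.0, max_len
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if ratio_at(mid) < spec.target_lambda:
            lo = mid
        else:
            hi = mid
    latex_mask = latex_at(hi)
    scar_mask = band & ~latex_mask
    lam = int(latex_mask.sum()) / int(scar_mask.sum())

    img = rng.normal(spec.bg_mean, spec.bg_sd, size=spec.shape)
    off_band = ~(band | latex_mask)
    speckle = (rng.random(spec.shape) < spec.bark_fraction) & off_band
    img[speckle] = rng.uniform(*spec.bark_range, size=int(speckle.sum()))
    img[scar_mask] = rng.normal(spec.scar_mean, spec.scar_sd, size=int(scar_mask.sum()))
    img[latex_mask] = rng.normal(spec.latex_mean, spec.latex_sd, size=int(latex_mask.sum()))
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticPanel(image=image, scar_mask=scar_mask, latex_mask=latex_mask, lam=lam)


_FIXTURES = {
    "bimodal": {0: 500, 255: 500},
    "five_delta": {160: 200, 180: 200, 200: 200, 220: 200, 250: 200},
    # 90% of the mass below gray 100, the remainder spread over 150-255
    "heavy_low_tail": {
        **{level: 45 for level in range(0, 100)},
        **{level: 20 for level in range(160, 170)},
        **{level: 10 for level in range(180, 200)},
        **{level: 20 for level in range(245, 250)},
    },
    "uniform": {level: 4 for level in range(256)},
}


def generate_histogram_fixture(name: str) -> GrayHistogram:
    """Named analytic histogram used across the oracle tests.

    Catalog: ``bimodal`` (equal deltas at 0 and 255), ``five_delta`` (equal
    mass at 160/180/200/220/250), ``heavy_low_tail`` (90% of the mass below
    gray 100, 10% spread over 150-255, the shape that defeats unrestricted
    thresholding), ``uniform`` (every level equally occupied).
    """
    try:
        counts = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}") from None
    return GrayHistogram.from_counts(counts)
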