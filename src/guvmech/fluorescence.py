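"""GUV fluorescence quantification and dithionite-quench classification.

Membrane fluorescence is measured as the mean intensity over a 5-pixel-thick
ring on the fitted vesicle contour minus the mean interior intensity
(sampled away from the membrane behind a 5-px guard band).  Dithionite only
reaches the externally exposed leaflet, so the post/pre net-intensity ratio
reports the sidedness of the NBD-labelled lipid: about one half when both
leaflets carry the dye, near zero when it is exclusively outer, near one
when exclusively inner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import AnalysisError
from .imaging import CircleFitResult, select_top_intensity_pixels, taubin_fit, RegionOfInterest

__all__ = [
    "ContourIntensity",
    "QuenchResult",
    "quantify_contour",
    "classify_quench",
    "compare_symmetry_intensity",
    "detect_guv_circle",
    "QUENCH_THRESHOLDS",
]

RING_HALF_WIDTH = 2.5   # ring thickness fixed at 5 px
INTERIOR_GUARD = 5.0    # px kept clear between ring and interior sample

#: (outer_only upper bound, both_leaflets interval, inner_only lower bound)
QUENCH_THRESHOLDS = {"outer": 0.15, "both_lo": 0.35, "both_hi": 0.65, "inner": 0.85}


@dataclass(frozen=True)
class ContourIntensity:
    ring_mean: float
    interior_mean: float
    circle: CircleFitResult | None = None

    @property
    def net(self) -> float:
        return self.ring_mean - self.interior_mean

    @property
    def pathological(self) -> bool:
        return self.net <= 0


@dataclass(frozen=True)
class QuenchResult:
    ratio: float
    classification: str  # both_leaflets | outer_only | inner_only | indeterminate


def quantify_contour(image, circle: CircleFitResult, pixel_size: float | None = None) -> ContourIntensity:
    """Ring-minus-interior intensity for a fitted vesicle circle.

    Ring: pixels with ``|dist(center) - r| <= 2.5`` px.  Interior: pixels
    with ``dist < r - 5`` px.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.hypot(xx - circle.cx, yy - circle.cy)
    ring = np.abs(d - circle.r) <= RING_HALF_WIDTH
    interior = d < circle.r - INTERIOR_GUARD
    if not ring.any():
        raise AnalysisError("empty contour ring: circle outside image?")
    if not interior.any():
        raise AnalysisError("empty interior region: vesicle too small for guard band")
    return ContourIntensity(
        ring_mean=float(image[ring].mean()),
        interior_mean=float(image[interior].mean()),
        circle=circle,
    )


def _net(x) -> float:
    return float(x.net) if hasattr(x, "net") else float(x)


def classify_quench(pre, post) -> QuenchResult:
    """Dye-sidedness classification from pre/post-quench net intensities."""
    pre_net = _net(pre)
    post_net = _net(post)
    if pre_net <= 0:
        raise AnalysisError("pre-quench net intensity must be positive")
    ratio = post_net / pre_net
    t = QUENCH_THRESHOLDS
    if ratio < t["outer"]:
        cls = "outer_only"
    elif t["both_lo"] <= ratio <= t["both_hi"]:
        cls = "both_leaflets"
    elif ratio > t["inner"]:
        cls = "inner_only"
    else:
        cls = "indeterminate"
    return QuenchResult(ratio=ratio, classification=cls)


def compare_symmetry_intensity(
    sym_nets: Sequence[float],
    asym_nets: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """median(asym)/median(sym) with a seeded bootstrap percentile CI.

    Returns ``(ratio, (ci_lo, ci_hi))``.
    """
    sym = np.asarray(sym_nets, dtype=np.float64)
    asym = np.asarray(asym_nets, dtype=np.float64)
    if sym.size < 3 or asym.size < 3:
        raise AnalysisError("need at least 3 vesicles per group")
    ratio = float(np.median(asym) / np.median(sym))
    rng = np.random.default_rng(seed)
    idx_s = rng.integers(0, sym.size, (n_boot, sym.size))
    idx_a = rng.integers(0, asym.size, (n_boot, asym.size))
    boot = np.median(asym[idx_a], axis=1) / np.median(sym[idx_s], axis=1)
    q = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(boot, q)), float(np.quantile(boot, 1.0 - q)))
    return ratio, ci


def detect_guv_circle(image, fraction: float = 2.0) -> CircleFitResult:
    """Circle of a free (non-aspirated) GUV from the brightest pixels."""
    image = np.asarray(image)
    h, w = image.shape
    roi = RegionOfInterest(0, 0, w, h, mouth_x=0.0, axis_y=0.0)
    pts = select_top_intensity_pixels(image, roi, fraction)
    return taubin_fit(pts)
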