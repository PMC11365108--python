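"""Vesicle image analysis for micropipette aspiration.

The measurement chain mirrors the standard semi-automated workflow: within a
user-supplied region of interest covering at least half of the vesicle, the
brightest 1, 2 and 3 % of pixels are selected, a Taubin algebraic circle fit
is run on each selection, and the three radii are averaged to give the vesicle
radius.  The aspirated tongue length is localised sub-pixel from the intensity
profile along the pipette axis.

Coordinate convention: 0-based pixel indices, pixel centers at integer
coordinates, x rightward (columns), y downward (rows).  The tongue lies on the
low-x side of the pipette-mouth plane ``mouth_x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError, DegenerateCircleError, TongueNotFoundError

__all__ = [
    "RegionOfInterest",
    "CircleFitResult",
    "VesicleGeometry",
    "select_top_intensity_pixels",
    "taubin_fit",
    "estimate_vesicle_radius",
    "measure_projection_length",
]

#: fractions (percent of brightest ROI pixels) fitted and averaged
RADIUS_FIT_FRACTIONS = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular ROI with the pipette reference coordinates.

    Bounds are 0-based and half-open: pixels with ``x0 <= x < x1`` and
    ``y0 <= y < y1`` belong to the ROI.  ``mouth_x`` is the x-coordinate of
    the pipette-mouth plane and ``axis_y`` the y-coordinate of the pipette
    axis, both in pixels (sub-pixel values allowed).
    """

    x0: int
    y0: int
    x1: int
    y1: int
    mouth_x: float
    axis_y: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("ROI bounds must satisfy x1 > x0 and y1 > y0")


@dataclass(frozen=True)
class CircleFitResult:
    cx: float
    cy: float
    r: float
    n_points: int
    fraction: float | None = None


@dataclass(frozen=True)
class VesicleGeometry:
    """Pipette radius, outer-segment radius and tongue length with errors (um)."""

    rp: float
    rv: float
    lp: float
    rp_err: float = 0.0
    rv_err: float = 0.0
    lp_err: float = 0.0

    def __post_init__(self) -> None:
        if self.rp <= 0:
            raise ValueError("pipette radius must be positive")
        if min(self.rp_err, self.rv_err, self.lp_err) < 0:
            raise ValueError("errors must be non-negative")


def select_top_intensity_pixels(image, roi: RegionOfInterest, fraction: float):
    """Coordinates of the brightest ``fraction`` % of pixels inside ``roi``.

    Returns an ``(n, 2)`` float array of (x, y) pixel coordinates, with
    ``n = ceil(fraction/100 * N_roi)``.  Ties at the threshold intensity are
    broken deterministically in row-major pixel order.
    """
    if not 0 < fraction <= 100:
        raise ValueError("fraction must be in (0, 100]")
    image = np.asarray(image)
    sub = image[roi.y0 : roi.y1, roi.x0 : roi.x1]
    if sub.size == 0:
        raise AnalysisError("empty ROI")
    n_take = math.ceil(fraction / 100.0 * sub.size)
    flat = sub.ravel()  # row-major
    order = np.argsort(-flat.astype(np.float64), kind="stable")
    idx = order[:n_take]
    ys, xs = np.unravel_index(idx, sub.shape)
    return np.column_stack((xs + roi.x0, ys + roi.y0)).astype(np.float64)


def taubin_fit(points) -> CircleFitResult:
    """Taubin algebraic circle fit.

    Minimises the gradient-normalised algebraic distance via the standard
    moment formulation (Newton iteration on the characteristic polynomial of
    the smallest root).  Exact for co-circular input; robust to noise with
    essentially no small-arc bias, which is why it is the fit of choice for
    partial vesicle contours.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateCircleError("need at least 3 points of shape (n, 2)")
    x = pts[:, 0]
    y = pts[:, 1]
    mx, my = x.mean(), y.mean()
    xc = x - mx
    yc = y - my
    z = xc * xc + yc * yc

    Mxx = np.mean(xc * xc)
    Myy = np.mean(yc * yc)
    Mxy = np.mean(xc * yc)
    Mxz = np.mean(xc * z)
    Myz = np.mean(yc * z)
    Mzz = np.mean(z * z)

    scale = Mxx + Myy
    cov_det = Mxx * Myy - Mxy * Mxy
    if scale <= 0 or cov_det <= 1e-14 * scale * scale:
        raise DegenerateCircleError("degenerate configuration: points are (near-)collinear")

    Mz = Mxx + Myy
    Var_z = Mzz - Mz * Mz
    A3 = 4.0 * Mz
    A2 = -3.0 * Mz * Mz - Mzz
    A1 = Var_z * Mz + 4.0 * cov_det * Mz - Mxz * Mxz - Myz * Myz
    A0 = (
        Mxz * (Mxz * Myy - Myz * Mxy)
        + Myz * (Myz * Mxx - Mxz * Mxy)
        - Var_z * cov_det
    )
    A22 = 2.0 * A2
    A33 = 3.0 * A3

    # Newton from 0: the smallest non-negative root is the Taubin solution.
    xnew = 0.0
    ynew = A0
    for _ in range(64):
        yold = ynew
        ynew = A0 + xnew * (A1 + xnew * (A2 + xnew * A3))
        if abs(ynew) > abs(yold):
            xnew = 0.0
            break
        dy = A1 + xnew * (A22 + xnew * A33)
        if dy == 0.0:
            break
        xold = xnew
        xnew = xold - ynew / dy
        if xnew < 0.0:
            xnew = 0.0
            break
        if abs(xnew - xold) <= 1e-14 * (abs(xnew) + 1e-300):
            break

    det = xnew * xnew - xnew * Mz + cov_det
    if det == 0.0:
        raise DegenerateCircleError("degenerate configuration: singular Taubin system")
    ccx = (Mxz * (Myy - xnew) - Myz * Mxy) / det / 2.0
    ccy = (Myz * (Mxx - xnew) - Mxz * Mxy) / det / 2.0
    r = math.sqrt(ccx * ccx + ccy * ccy + Mz)
    return CircleFitResult(cx=ccx + mx, cy=ccy + my, r=r, n_points=pts.shape[0])


@dataclass(frozen=True)
class RadiusDiagnostics:
    fits: tuple[CircleFitResult, ...] = field(default_factory=tuple)


def estimate_vesicle_radius(image, roi: RegionOfInterest, pixel_size: float):
    """Vesicle radius (um) averaged over Taubin fits at 1, 2 and 3 % fractions.

    Returns ``(rv_um, rv_err_um, diagnostics)``.  The error is the sample SD
    of the three radii, floored at half a pixel (the three-sample SD can be
    degenerately zero).
    """
    fits = []
    for frac in RADIUS_FIT_FRACTIONS:
        pts = select_top_intensity_pixels(image, roi, frac)
        try:
            fit = taubin_fit(pts)
        except DegenerateCircleError as exc:
            raise DegenerateCircleError(
                f"degenerate circle fit at fraction {frac}%: {exc}"
            ) from exc
        fits.append(CircleFitResult(fit.cx, fit.cy, fit.r, fit.n_points, frac))
    radii = np.array([f.r for f in fits])
    rv = radii.mean() * pixel_size
    sd = radii.std(ddof=1) * pixel_size
    rv_err = max(sd, 0.5 * pixel_size)
    return rv, rv_err, RadiusDiagnostics(fits=tuple(fits))


def _column_scores(image, roi: RegionOfInterest | None, mouth_x, axis_y, rp_px):
    """Per-column tongue-band score: mean of the 3 brightest band pixels."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    y_lo = max(0, int(math.floor(axis_y - rp_px / 2.0)))
    y_hi = min(h, int(math.ceil(axis_y + rp_px / 2.0)) + 1)
    x_lo = 0 if roi is None else max(0, roi.x0)
    x_hi = int(math.floor(mouth_x))
    if y_hi - y_lo < 1 or x_hi - x_lo < 3:
        raise TongueNotFoundError("tongue band empty")
    band = image[y_lo:y_hi, x_lo:x_hi]
    k = min(3, band.shape[0])
    top = np.sort(band, axis=0)[-k:, :]
    return top.mean(axis=0), x_lo


def estimate_line_spread(
    image,
    circle: CircleFitResult,
    roi: RegionOfInterest | None = None,
    half_window: float = 6.0,
):
    """Gaussian line-spread width (px) of the membrane from its radial profile.

    Intensity-weighted second moment of (distance - r) over an annulus around
    the fitted circle, with the background taken from the annulus edges.  When
    ``roi`` is given the annulus is restricted to it (keeps the pipette out of
    the profile).  Used to self-calibrate the tongue-tip fit on the same frame.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    y0 = max(0, int(circle.cy - circle.r - half_window - 1))
    y1 = min(h, int(circle.cy + circle.r + half_window + 2))
    x0 = max(0, int(circle.cx - circle.r - half_window - 1))
    x1 = min(w, int(circle.cx + circle.r + half_window + 2))
    if roi is not None:
        x0, x1 = max(x0, roi.x0), min(x1, roi.x1)
        y0, y1 = max(y0, roi.y0), min(y1, roi.y1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    d = np.hypot(xx - circle.cx, yy - circle.cy) - circle.r
    sel = np.abs(d) <= half_window
    if not sel.any():
        raise AnalysisError("empty annulus for line-spread estimation")
    vals = image[y0:y1, x0:x1][sel]
    dd = d[sel]
    bg = float(np.median(vals[np.abs(dd) >= 0.8 * half_window]))
    wgt = np.clip(vals - bg, 0.0, None)
    if wgt.sum() <= 0:
        raise AnalysisError("no membrane signal above background in annulus")
    mu = float(np.sum(wgt * dd) / wgt.sum())
    var = float(np.sum(wgt * (dd - mu) ** 2) / wgt.sum())
    return math.sqrt(max(var, 1e-4))


def measure_projection_length(
    image,
    roi: RegionOfInterest | None,
    pixel_size: float,
    rp_um: float,
    mouth_x: float | None = None,
    axis_y: float | None = None,
    ring_sigma: float | None = None,
):
    """Aspirated tongue length Lp (um) with a fixed one-pixel uncertainty.

    Within a band of half-width Rp/2 around the pipette axis and x < mouth_x,
    each column is scored by its three brightest pixels.  The tongue tip is
    the extreme (lowest-x) column whose score exceeds half the band's peak;
    a quadratic fit to the log of the Gaussian leading edge refines the tip
    position to sub-pixel accuracy.
    """
    if mouth_x is None:
        if roi is None:
            raise ValueError("mouth_x required when roi is None")
        mouth_x = roi.mouth_x
    if axis_y is None:
        if roi is None:
            raise ValueError("axis_y required when roi is None")
        axis_y = roi.axis_y
    rp_px = rp_um / pixel_size
    score, x_lo = _column_scores(image, roi, mouth_x, axis_y, rp_px)
    xs = np.arange(x_lo, x_lo + score.size, dtype=np.float64)

    # decisions (peak, thresholds, column ranges) run on a lightly smoothed
    # profile so single noisy columns cannot derail them
    kernel = np.exp(-0.5 * (np.arange(-3, 4) / 1.0) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(score, kernel, mode="same")

    peak = float(sm.max())
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    noise = 1.4826 * mad
    if peak <= 0 or peak - med <= max(3.0 * noise, 1e-12):
        raise TongueNotFoundError("no band pixel above threshold: tongue not found")

    thr = med + 0.5 * (peak - med)
    above = np.flatnonzero(sm >= thr)
    i_half = int(above.min())
    # linear interpolation of the half-max crossing (fallback tip estimate)
    if i_half > 0 and sm[i_half] > sm[i_half - 1]:
        x_tip = xs[i_half] - (sm[i_half] - thr) / (sm[i_half] - sm[i_half - 1])
    else:
        x_tip = xs[i_half]

    # refine on the Gaussian leading edge of the raw profile:
    # score(x) = b + A*exp(-(x - x_tip)^2 / (2 s^2)) for x left of the tip
    i_peak = int(np.flatnonzero(sm >= med + 0.99 * (peak - med)).min())
    lo_rel = med + 0.04 * (peak - med)
    hi_rel = med + 0.995 * (peak - med)
    edge = []
    for i in range(i_peak - 1, -1, -1):
        s = sm[i]
        if s >= hi_rel:
            continue
        if s <= lo_rel:
            break
        edge.append(i)
    edge.reverse()
    if ring_sigma is not None and len(edge) >= 2:
        # line-spread known: 2-parameter matched fit of the leading edge
        from scipy.optimize import curve_fit

        ex = xs[edge]
        ey = score[edge]
        sg = float(ring_sigma)

        def model(x, a, xt):
            return med + a * np.exp(-((x - xt) ** 2) / (2.0 * sg * sg))

        try:
            popt, _ = curve_fit(
                model, ex, ey,
                p0=(peak - med, x_tip),
                bounds=((0.0, x_tip - 3.0), (np.inf, x_tip + 4.0)),
                maxfev=2000,
            )
            x_tip = float(popt[1])
        except RuntimeError:
            pass
    elif len(edge) >= 4:
        from scipy.optimize import curve_fit

        ex = xs[edge]
        ey = score[edge]

        def model(x, b, a, xt, sg):
            return b + a * np.exp(-((x - xt) ** 2) / (2.0 * sg * sg))

        try:
            popt, _ = curve_fit(
                model, ex, ey,
                p0=(med, peak - med, x_tip, 1.5),
                bounds=(
                    (-np.inf, 0.0, x_tip - 3.0, 0.3),
                    (np.inf, np.inf, x_tip + 4.0, 8.0),
                ),
                maxfev=2000,
            )
            x_tip = float(popt[2])
        except RuntimeError:
            pass
    elif len(edge) >= 3:
        ex = xs[edge]
        sv = np.maximum(score[edge] - med, 1e-9)
        c2, c1, _ = np.polyfit(ex, np.log(sv), 2, w=sv)
        if c2 < 0:
            x_vertex = -c1 / (2.0 * c2)
            if ex.min() - 1.5 <= x_vertex <= x_tip + 3.0:
                x_tip = x_vertex
    lp = (mouth_x - x_tip) * pixel_size
    return lp, 1.0 * pixel_size
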