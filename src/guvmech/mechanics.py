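"""Micropipette-aspiration mechanics: tension, area strain and K_A extraction.

An aspirated vesicle is modelled as a spherical outer segment of radius Rv
joined, across the pipette mouth of inner radius Rp, to a cylindrical tongue
of length Lp capped by a hemisphere.  The membrane tension follows from the
Laplace relation

    tau = dP * Rp / (2 * (1 - Rp / Rv)),

and the relative area expansion alpha = (A - A0) / A0 is referenced to the
first (prestressed) aspiration step.  In the enthalpic (high-tension) regime
tau is linear in alpha with slope K_A, the area compressibility (stretching
elasticity) modulus.

Units: lengths in um, pressures in Pa, tensions and K_A in mN/m.  All
uncertainties are propagated to first order by numeric central differences
(relative step 1e-6), the differential approach.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .exceptions import AnalysisError, GeometryError, GeometryInfeasibleError
from .imaging import VesicleGeometry

__all__ = [
    "PressureStep",
    "TensionAreaPoint",
    "ElasticityModel",
    "ElasticityFitResults",
    "tension",
    "vesicle_area_volume",
    "solve_geometry",
    "area_strain",
    "analyze_series",
    "fit_ka",
    "hysteresis_check",
    "HysteresisResult",
]

logger = logging.getLogger(__name__)

_REL_STEP = 1e-6  # relative step of the central finite differences


@dataclass(frozen=True)
class PressureStep:
    """One suction-pressure setting (Pa)."""

    dp: float
    dp_err: float = 0.0
    step: int = 0


@dataclass(frozen=True)
class TensionAreaPoint:
    """One point of the tension-area-expansion plot."""

    tau: float
    tau_err: float
    alpha: float
    alpha_err: float
    step: int = 0


def propagate_error(f, values, errors, rel_step: float = _REL_STEP) -> float:
    """First-order error propagation with numeric central differences.

    sigma_f^2 = sum_i (df/dx_i * sigma_i)^2, each partial evaluated with a
    central difference of relative step ``rel_step``.
    """
    values = list(map(float, values))
    var = 0.0
    for i, (v, s) in enumerate(zip(values, errors)):
        if s == 0.0:
            continue
        h = rel_step * (abs(v) if v != 0.0 else 1.0)
        hi = list(values)
        lo = list(values)
        hi[i] = v + h
        lo[i] = v - h
        g = (f(*hi) - f(*lo)) / (2.0 * h)
        var += (g * s) ** 2
    return math.sqrt(var)


def _tension_value(dp: float, rp: float, rv: float) -> float:
    # Pa * um = 1e-3 mN/m
    return dp * rp / (2.0 * (1.0 - rp / rv)) * 1e-3


def tension(dp: PressureStep, geom: VesicleGeometry):
    """Membrane tension (mN/m) and its propagated uncertainty."""
    if geom.rv <= geom.rp:
        raise GeometryError("geometry outside aspiration regime: rv <= rp")
    tau = _tension_value(dp.dp, geom.rp, geom.rv)
    tau_err = propagate_error(
        _tension_value,
        (dp.dp, geom.rp, geom.rv),
        (dp.dp_err, geom.rp_err, geom.rv_err),
    )
    return tau, tau_err


def _area_volume_raw(rv: float, rp: float, lp: float):
    """Area/volume of the aspirated shape, without regime validation.

    Outer segment: the major spherical cap of height h = Rv + sqrt(Rv^2-Rp^2).
    Tongue: open cylinder of length Lp - Rp plus a hemispherical cap.
    """
    h = rv + math.sqrt(max(rv * rv - rp * rp, 0.0))
    area = 2.0 * math.pi * rv * h
    volume = math.pi * h * h / 3.0 * (3.0 * rv - h)
    area += 2.0 * math.pi * rp * (lp - rp) + 2.0 * math.pi * rp * rp
    volume += math.pi * rp * rp * (lp - rp) + 2.0 / 3.0 * math.pi * rp**3
    return area, volume


def vesicle_area_volume(geom: VesicleGeometry):
    """Total membrane area (um^2) and enclosed volume (um^3)."""
    if geom.rv <= geom.rp:
        raise GeometryError("aspiration geometry requires rv > rp")
    if geom.lp < geom.rp * (1.0 - 1e-9):
        raise GeometryError("aspiration geometry requires lp >= rp (hemisphere tip)")
    return _area_volume_raw(geom.rv, geom.rp, max(geom.lp, geom.rp))


def _lp_from_volume(rv: float, rp: float, volume: float) -> float:
    h = rv + math.sqrt(max(rv * rv - rp * rp, 0.0))
    v_cap = math.pi * h * h / 3.0 * (3.0 * rv - h)
    v_tongue = volume - v_cap
    return rp + (v_tongue - 2.0 / 3.0 * math.pi * rp**3) / (math.pi * rp * rp)


def solve_geometry(area: float, volume: float, rp: float):
    """Invert (area, volume, Rp) -> (Rv, Lp) for the aspirated shape.

    Rv is found by bracketed root-finding on the area residual; for each trial
    Rv the tongue length follows linearly from the volume constraint.  Raises
    :class:`GeometryInfeasibleError` when no aspirated shape matches.
    """
    if area <= 0 or volume <= 0 or rp <= 0:
        raise ValueError("area, volume and rp must be positive")
    r_equiv = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    if area < 4.0 * math.pi * r_equiv * r_equiv * (1.0 - 1e-12):
        raise GeometryInfeasibleError(
            "geometry infeasible: area below that of the volume-equivalent sphere"
        )

    def resid(rv: float) -> float:
        lp = _lp_from_volume(rv, rp, volume)
        a, _ = _area_volume_raw(rv, rp, lp)
        return a - area

    rv_lo = rp * (1.0 + 1e-9)
    rv_hi = math.sqrt(area / (4.0 * math.pi)) * (1.0 + 1e-9)
    grid = np.linspace(rv_lo, max(rv_hi, rv_lo * (1.0 + 1e-6)), 256)
    vals = np.array([resid(rv) for rv in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0:
        raise GeometryInfeasibleError("geometry infeasible: no root in bracket")
    i = int(sign_change[-1])  # root with the largest Rv (near-spherical branch)
    rv = brentq(resid, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16, maxiter=200)
    lp = _lp_from_volume(rv, rp, volume)
    # lp comes from a difference of near-equal volumes; its absolute noise
    # floor is the cancellation error divided by the pipette cross-section
    lp_tol = max(1e-7 * rp, 1e-9 * volume / (math.pi * rp * rp))
    if lp < rp - lp_tol:
        raise GeometryInfeasibleError(
            "geometry infeasible: tongue shorter than the hemispherical cap"
        )
    return rv, max(lp, rp)


def _alpha_value(area: float, area0: float) -> float:
    return (area - area0) / area0


def area_strain(area, area_err, area0, area0_err):
    """Relative area expansion alpha = (A - A0)/A0 with propagated error."""
    if area0 <= 0:
        raise ValueError("reference area must be positive")
    alpha = _alpha_value(area, area0)
    alpha_err = propagate_error(
        _alpha_value, (area, area0), (area_err, area0_err)
    )
    return alpha, alpha_err


def _series_alpha(rv, lp, rv0, lp0, rp):
    a, _ = _area_volume_raw(rv, rp, lp)
    a0, _ = _area_volume_raw(rv0, rp, lp0)
    return (a - a0) / a0


def analyze_series(
    geometries: Sequence[VesicleGeometry],
    pressures: Sequence[PressureStep],
) -> list[TensionAreaPoint]:
    """Tension-area points for one aspiration series.

    The first step is the post-prestress reference defining A0; each later
    step contributes one point.  Steps outside the aspiration regime
    (rv <= rp or lp < rp) are excluded and logged.  The alpha error budget
    accounts for the shared pipette radius and the reference-step geometry.
    """
    if len(geometries) != len(pressures):
        raise ValueError("geometries and pressures must have equal length")
    if len(geometries) < 3:
        raise AnalysisError("need at least 3 steps (reference + 2 points)")
    ref = geometries[0]
    if ref.rv <= ref.rp or ref.lp < ref.rp * (1.0 - 1e-9):
        raise AnalysisError("reference step outside aspiration regime")
    points: list[TensionAreaPoint] = []
    for geom, press in zip(geometries[1:], pressures[1:]):
        if geom.rv <= geom.rp or geom.lp < geom.rp * (1.0 - 1e-9):
            logger.warning(
                "step %d outside aspiration regime (rv=%.3f, rp=%.3f, lp=%.3f); excluded",
                press.step, geom.rv, geom.rp, geom.lp,
            )
            continue
        tau, tau_err = tension(press, geom)
        alpha = _series_alpha(geom.rv, geom.lp, ref.rv, ref.lp, geom.rp)
        alpha_err = propagate_error(
            _series_alpha,
            (geom.rv, geom.lp, ref.rv, ref.lp, geom.rp),
            (geom.rv_err, geom.lp_err, ref.rv_err, ref.lp_err, geom.rp_err),
        )
        points.append(TensionAreaPoint(tau, tau_err, alpha, alpha_err, press.step))
    if len(points) < 2:
        raise AnalysisError("fewer than 3 valid steps in series")
    return points


@dataclass(frozen=True)
class ElasticityFitResults:
    """Weighted-regression estimate of the stretching elasticity modulus."""

    ka: float
    ka_err: float
    intercept: float
    intercept_err: float
    n_points: int
    r_squared: float
    tau_min: float

    def summary(self) -> str:
        lines = [
            "Stretching elasticity fit (tau = K_A * alpha + c)",
            "-" * 49,
            f"K_A        {self.ka:10.1f} +/- {self.ka_err:.1f} mN/m",
            f"intercept  {self.intercept:10.4f} +/- {self.intercept_err:.4f} mN/m",
            f"n_points   {self.n_points:10d}",
            f"R^2        {self.r_squared:10.5f}",
            f"tau_min    {self.tau_min:10.2f} mN/m",
        ]
        return "\n".join(lines)

    def predict(self, alpha):
        return self.intercept + self.ka * np.asarray(alpha)

    def plot(self, points=None, ax=None):
        """Tension-area-expansion plot with the fitted line.

        ``points`` is an optional sequence of :class:`TensionAreaPoint` to
        scatter with error bars.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if points:
            ax.errorbar(
                [p.alpha for p in points],
                [p.tau for p in points],
                xerr=[p.alpha_err for p in points],
                yerr=[p.tau_err for p in points],
                fmt="o", ms=4, capsize=2, label="data",
            )
            amax = max(p.alpha for p in points)
        else:
            amax = 0.02
        grid = np.linspace(0.0, amax * 1.05, 50)
        ax.plot(
            grid, self.predict(grid), "-",
            label=f"$K_A$ = {self.ka:.0f} $\\pm$ {self.ka_err:.0f} mN/m",
        )
        ax.set_xlabel(r"area expansion $\alpha$")
        ax.set_ylabel(r"tension $\tau$ (mN/m)")
        ax.legend()
        return ax


class ElasticityModel:
    """Linear model of membrane tension versus area expansion.

    Points with tau below ``tau_min`` (entropic/low-tension regime) are
    excluded; the intercept is left free because alpha is referenced to an
    arbitrary prestressed state.

    Two regression orientations are offered.  The default, ``"inverse"``,
    regresses alpha on tau and reports K_A as the inverted slope: in
    aspiration the tension derives from the controlled suction pressure and
    is far more precise than the image-derived strain, and placing the noisy
    variable on the ordinate avoids the regression-dilution (attenuation)
    bias that a direct tau-on-alpha fit incurs.  ``"direct"`` performs the
    conventional WLS of tau on alpha with weights 1/tau_err^2 (uniform when
    all tension errors vanish); alpha errors are never used as weights.
    Both orientations agree exactly on noise-free data.
    """

    def __init__(
        self,
        points: Sequence[TensionAreaPoint],
        tau_min: float = 0.5,
        orientation: str = "inverse",
    ):
        if orientation not in ("inverse", "direct"):
            raise ValueError("orientation must be 'inverse' or 'direct'")
        self.points = list(points)
        self.tau_min = float(tau_min)
        self.orientation = orientation

    @classmethod
    def from_dataframe(cls, df, tau_min: float = 0.5, orientation: str = "inverse"):
        pts = [
            TensionAreaPoint(
                float(r.tau), float(getattr(r, "tau_err", 0.0)),
                float(r.alpha), float(getattr(r, "alpha_err", 0.0)),
                int(getattr(r, "step", i)),
            )
            for i, r in enumerate(df.itertuples(index=False))
        ]
        return cls(pts, tau_min=tau_min, orientation=orientation)

    def fit(self) -> ElasticityFitResults:
        import statsmodels.api as sm

        sel = [p for p in self.points if p.tau >= self.tau_min]
        if len(sel) < 3:
            raise AnalysisError(
                f"fewer than 3 points with tau >= tau_min={self.tau_min} mN/m"
            )
        tau = np.array([p.tau for p in sel])
        alpha = np.array([p.alpha for p in sel])
        terr = np.array([p.tau_err for p in sel])
        if np.all(terr == 0.0):
            weights = np.ones_like(tau)
        else:
            floor = terr[terr > 0].min()
            weights = 1.0 / np.maximum(terr, floor) ** 2

        if self.orientation == "direct":
            res = sm.WLS(tau, sm.add_constant(alpha), weights=weights).fit()
            ka = float(res.params[1])
            ka_err = float(res.bse[1])
            intercept = float(res.params[0])
            intercept_err = float(res.bse[0])
        else:
            res = sm.OLS(alpha, sm.add_constant(tau)).fit()
            a0, a1 = res.params
            sa0, sa1 = res.bse
            if a1 == 0:
                raise AnalysisError("degenerate fit: alpha does not vary with tau")
            ka = float(1.0 / a1)
            ka_err = float(sa1 / a1**2)
            # tau = alpha/a1 - a0/a1
            intercept = float(-a0 / a1)
            cov = res.cov_params()
            g = np.array([-1.0 / a1, a0 / a1**2])  # d(-a0/a1)/d(a0, a1)
            intercept_err = float(math.sqrt(max(g @ np.asarray(cov) @ g, 0.0)))
        return ElasticityFitResults(
            ka=ka,
            ka_err=ka_err,
            intercept=intercept,
            intercept_err=intercept_err,
            n_points=len(sel),
            r_squared=float(res.rsquared),
            tau_min=self.tau_min,
        )


def fit_ka(
    points: Sequence[TensionAreaPoint],
    tau_min: float = 0.5,
    orientation: str = "inverse",
) -> ElasticityFitResults:
    """Convenience wrapper: ``ElasticityModel(points, tau_min, orientation).fit()``."""
    return ElasticityModel(points, tau_min=tau_min, orientation=orientation).fit()


@dataclass(frozen=True)
class HysteresisResult:
    max_delta_alpha: float
    passed: bool
    threshold: float


def hysteresis_check(
    ascending: Sequence[TensionAreaPoint],
    descending: Sequence[TensionAreaPoint],
    threshold: float = 0.002,
) -> HysteresisResult:
    """Maximum |delta alpha| between pressure branches at matched tensions.

    Both branches are linearly interpolated as alpha(tau) over their common
    tension range; agreement rules out membrane-pipette adhesion and drift.
    """
    if not ascending or not descending:
        raise AnalysisError("both branches must be non-empty")

    def branch(points):
        tau = np.array([p.tau for p in points])
        alpha = np.array([p.alpha for p in points])
        order = np.argsort(tau)
        return tau[order], alpha[order]

    ta, aa = branch(ascending)
    td, ad = branch(descending)
    lo = max(ta.min(), td.min())
    hi = min(ta.max(), td.max())
    if lo > hi:
        raise AnalysisError("branches have non-overlapping tension ranges")
    grid = np.unique(np.clip(np.concatenate([ta, td, [lo, hi]]), lo, hi))
    delta = np.interp(grid, ta, aa) - np.interp(grid, td, ad)
    max_delta = float(np.max(np.abs(delta)))
    return HysteresisResult(max_delta, max_delta <= threshold, threshold)
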