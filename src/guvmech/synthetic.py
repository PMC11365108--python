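"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the inputs of the analysis chain:

* :func:`gen_aspiration_series` — a volume-conserving micropipette-aspiration
  series driven by a prescribed stretching modulus.  For each suction
  pressure the tension follows the Laplace relation, the strain from
  ``alpha = tau / K_A``, and the aspirated geometry (Rv, Lp) from inverting
  the area/volume equations at constant vesicle volume; the frame is then
  rendered as a ring-shaped fluorescence image with shot-noise statistics.
* :func:`gen_bilayer_frames` — Gaussian-jittered phosphorus planes with
  chain pseudo-atoms filling toward the midplane (prescribed leaflet-overlap
  width) and optional octane in the bilayer core.
* :func:`gen_population` / :func:`gen_area_series` — per-vesicle measurement
  tables for the population statistics, and equilibrium box-area series with
  variance kB*T*<A>/K_A for the fluctuation estimator.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.constants import k as _KB

from .bilayer import BilayerFrame
from .exceptions import CanvasOverflowError, GeometryInfeasibleError
from .imaging import VesicleGeometry
from .mechanics import PressureStep, _tension_value, solve_geometry
from .pipeline import AnalysisConfig

__all__ = [
    "AspirationSimSpec",
    "BilayerSimSpec",
    "PopulationSpec",
    "GroupSpec",
    "AspirationStep",
    "AspirationSeries",
    "default_aspiration_spec",
    "gen_aspiration_series",
    "render_aspirated_guv",
    "render_ring_image",
    "gen_bilayer_frames",
    "gen_area_series",
    "gen_population",
    "PHOSPHORUS_MASS",
    "CHAIN_PSEUDOATOM_MASS",
    "OCTANE_MASS",
    "CHAIN_ATOMS_PER_LIPID",
]

# Lipid mass model: one phosphorus atom plus 16 chain pseudo-atoms per lipid,
# masses summing to a POPC-like 760 amu; octane is one pseudo-atom.
PHOSPHORUS_MASS = 30.974
CHAIN_ATOMS_PER_LIPID = 16
LIPID_MASS = 760.0
CHAIN_PSEUDOATOM_MASS = (LIPID_MASS - PHOSPHORUS_MASS) / CHAIN_ATOMS_PER_LIPID
OCTANE_MASS = 114.23


@dataclass(frozen=True)
class AspirationSimSpec:
    """Study conditions for one synthetic aspiration experiment.

    ``ka_true`` in mN/m, lengths in um, pressures in Pa, ``pixel_size`` in
    um/px, ``ring_sigma`` (membrane line spread) in px, ``snr`` the
    peak-signal-to-noise ratio (``inf`` disables noise).
    """

    ka_true: float
    area0: float
    volume: float
    rp: float
    pressures: tuple[float, ...]
    pixel_size: float = 0.2
    ring_sigma: float = 1.5
    snr: float = math.inf
    seed: int = 0
    shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.ka_true <= 0:
            raise ValueError("ka_true must be positive")
        if self.rp <= 0:
            raise ValueError("rp must be positive")
        p = np.asarray(self.pressures, dtype=float)
        if p.size and np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")
        r_a = math.sqrt(self.area0 / (4.0 * math.pi))
        if 4.0 / 3.0 * math.pi * r_a**3 < self.volume:
            raise ValueError(
                "area0 and volume inadmissible: sphere of area area0 holds less volume"
            )


def default_aspiration_spec(
    ka_true: float = 500.0,
    seed: int = 0,
    snr: float = math.inf,
    n_steps: int = 10,
) -> AspirationSimSpec:
    """Default study conditions: a 10-um GUV, 3-um pipette, tensions
    spanning the enthalpic regime (~0.5-6.5 mN/m over ``n_steps`` steps)."""
    r0 = 10.0
    return AspirationSimSpec(
        ka_true=ka_true,
        area0=4.0 * math.pi * r0**2,
        volume=0.97 * 4.0 / 3.0 * math.pi * r0**3,
        rp=3.0,
        pressures=tuple(np.linspace(250.0, 3000.0, n_steps)),
        seed=seed,
        snr=snr,
    )


def _contour_distance(xx, yy, rv, rp, lp, mouth_x, axis_y):
    """Exact distance from each pixel to the aspirated-vesicle contour (px)."""
    ax = mouth_x + math.sqrt(rv * rv - rp * rp)
    # outer spherical arc (x >= mouth_x)
    dx = xx - ax
    dy = yy - axis_y
    rho = np.hypot(dx, dy)
    cmin = (mouth_x - ax) / rv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(rho > 0, dx / np.maximum(rho, 1e-300), 1.0)
    d_arc = np.where(
        cosang >= cmin,
        np.abs(rho - rv),
        np.minimum(
            np.hypot(xx - mouth_x, yy - (axis_y - rp)),
            np.hypot(xx - mouth_x, yy - (axis_y + rp)),
        ),
    )
    # pipette walls: two segments y = axis_y +/- rp, x in [x_cyl, mouth_x]
    x_cyl = mouth_x - (lp - rp)
    xs = np.clip(xx, x_cyl, mouth_x)
    d_lines = np.minimum(
        np.hypot(xx - xs, yy - (axis_y - rp)),
        np.hypot(xx - xs, yy - (axis_y + rp)),
    )
    # hemispherical tongue tip (x <= x_cyl)
    dx2 = xx - x_cyl
    rho2 = np.hypot(dx2, dy)
    d_tip = np.where(
        dx2 <= 0,
        np.abs(rho2 - rp),
        np.minimum(
            np.hypot(xx - x_cyl, yy - (axis_y - rp)),
            np.hypot(xx - x_cyl, yy - (axis_y + rp)),
        ),
    )
    return np.minimum(np.minimum(d_arc, d_lines), d_tip)


def render_aspirated_guv(
    geom: VesicleGeometry,
    pixel_size: float,
    ring_sigma: float,
    snr: float,
    seed,
    shape: tuple[int, int] = (512, 512),
    mouth_x: float | None = None,
    axis_y: float | None = None,
    peak: float = 3000.0,
    background_frac: float = 0.05,
) -> np.ndarray:
    """Render one aspirated-GUV fluorescence frame as a 16-bit image.

    The membrane contour (outer arc, pipette walls, tongue-tip half ring) is
    spread with a Gaussian line profile of width ``ring_sigma``; noise is a
    Gaussian approximation to shot noise with variance proportional to the
    local intensity, scaled so that peak/sigma_noise = ``snr``.
    """
    h, w = shape
    rv = geom.rv / pixel_size
    rp = geom.rp / pixel_size
    lp = geom.lp / pixel_size
    if axis_y is None:
        axis_y = (h - 1) / 2.0
    if mouth_x is None:
        extent = lp + math.sqrt(rv * rv - rp * rp) + rv
        mouth_x = (w - extent) / 2.0 + lp
    margin = 4.0 * ring_sigma + 1.0
    x_right = mouth_x + math.sqrt(rv * rv - rp * rp) + rv
    x_left = mouth_x - lp
    if (
        x_left - margin < 0
        or x_right + margin > w - 1
        or axis_y - rv - margin < 0
        or axis_y + rv + margin > h - 1
    ):
        raise CanvasOverflowError("rendered contour does not fit on the canvas")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = _contour_distance(xx, yy, rv, rp, lp, mouth_x, axis_y)
    img = background_frac * peak + peak * np.exp(-(d * d) / (2.0 * ring_sigma**2))
    if math.isfinite(snr):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sigma = np.sqrt(img / peak) * (peak / snr)
        img = img + rng.standard_normal(img.shape) * sigma
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_ring_image(
    radius_px: float,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] | None = None,
    sigma: float = 1.5,
    amplitude: float = 100.0,
    background: float = 10.0,
    profile: str = "gaussian",
    ring_half_width: float = 2.5,
    snr: float = math.inf,
    seed: int = 0,
) -> np.ndarray:
    """Free (non-aspirated) GUV: a single ring on a uniform background.

    ``profile='tophat'`` renders a flat ring of half-width
    ``ring_half_width`` px (net contour intensity equals ``amplitude``
    exactly up to discretisation); ``'gaussian'`` uses a Gaussian line
    spread of width ``sigma``.
    """
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.hypot(xx - cx, yy - cy) - radius_px
    if profile == "tophat":
        img = background + amplitude * (np.abs(d) <= ring_half_width)
    elif profile == "gaussian":
        img = background + amplitude * np.exp(-(d * d) / (2.0 * sigma**2))
    else:
        raise ValueError("profile must be 'gaussian' or 'tophat'")
    if math.isfinite(snr):
        rng = np.random.default_rng(seed)
        ref = background + amplitude
        sigma_n = np.sqrt(np.maximum(img, 0.0) / ref) * (ref / snr)
        img = img + rng.standard_normal(img.shape) * sigma_n
    return img


@dataclass(frozen=True)
class AspirationStep:
    pressure: PressureStep
    geometry: VesicleGeometry
    tau: float
    alpha: float
    image: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class AspirationSeries:
    spec: AspirationSimSpec
    steps: tuple[AspirationStep, ...]
    config: AnalysisConfig

    @property
    def images(self) -> list[np.ndarray]:
        return [s.image for s in self.steps]

    @property
    def pressures(self) -> list[PressureStep]:
        return [s.pressure for s in self.steps]

    @property
    def geometries(self) -> list[VesicleGeometry]:
        return [s.geometry for s in self.steps]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.pressure.step for s in self.steps],
                "pressure_pa": [s.pressure.dp for s in self.steps],
                "rv_um": [s.geometry.rv for s in self.steps],
                "lp_um": [s.geometry.lp for s in self.steps],
                "tau_mn_per_m": [s.tau for s in self.steps],
                "alpha": [s.alpha for s in self.steps],
            }
        )


def _solve_step(spec: AspirationSimSpec, pressure: float):
    """Self-consistent (tau, alpha, Rv, Lp) for one suction pressure.

    tau depends on Rv through the Laplace relation while Rv follows from the
    strained area at constant volume, so the pair is iterated to fixed point.
    """
    rv = math.sqrt(spec.area0 / (4.0 * math.pi))
    tau = alpha = 0.0
    lp = spec.rp
    for _ in range(200):
        tau = _tension_value(pressure, spec.rp, rv)
        alpha = tau / spec.ka_true
        area = spec.area0 * (1.0 + alpha)
        try:
            rv_new, lp = solve_geometry(area, spec.volume, spec.rp)
        except GeometryInfeasibleError as exc:
            raise GeometryInfeasibleError(
                f"geometry infeasible at pressure {pressure} Pa: {exc}"
            ) from exc
        if abs(rv_new - rv) <= 1e-13 * rv:
            rv = rv_new
            break
        rv = rv_new
    return tau, alpha, rv, lp


def gen_aspiration_series(spec: AspirationSimSpec) -> AspirationSeries:
    """Forward-simulate and render a full aspiration series."""
    rng = np.random.default_rng(spec.seed)
    truths = [_solve_step(spec, p) for p in spec.pressures]
    if not truths:
        return AspirationSeries(
            spec=spec,
            steps=(),
            config=AnalysisConfig(
                pixel_size_um=spec.pixel_size,
                rp_um=spec.rp,
                rp_err_um=0.05,
                mouth_x_px=0.0,
                axis_y_px=0.0,
                roi_px=(0, 0, 1, 1),
            ),
        )
    h, w = spec.shape
    px = spec.pixel_size
    rv_max = max(t[2] for t in truths) / px
    lp_max = max(t[3] for t in truths) / px
    rp_px = spec.rp / px
    extent = lp_max + math.sqrt(rv_max**2 - rp_px**2) + rv_max
    mouth_x = (w - extent) / 2.0 + lp_max
    axis_y = (h - 1) / 2.0

    steps = []
    for i, (pressure, (tau, alpha, rv, lp)) in enumerate(zip(spec.pressures, truths)):
        geom = VesicleGeometry(rp=spec.rp, rv=rv, lp=lp)
        image = render_aspirated_guv(
            geom, px, spec.ring_sigma, spec.snr,
            seed=int(rng.integers(2**31)),
            shape=spec.shape, mouth_x=mouth_x, axis_y=axis_y,
        )
        steps.append(
            AspirationStep(
                pressure=PressureStep(dp=pressure, dp_err=0.0, step=i),
                geometry=geom, tau=tau, alpha=alpha, image=image,
            )
        )

    pad = 5.0 * spec.ring_sigma + 3.0
    ax_center = mouth_x + math.sqrt(rv_max**2 - rp_px**2)
    roi = (
        int(math.ceil(mouth_x)) + 3,
        max(0, int(math.floor(axis_y - rv_max - pad))),
        min(w, int(math.ceil(ax_center + rv_max + pad))),
        min(h, int(math.ceil(axis_y + rv_max + pad))),
    )
    config = AnalysisConfig(
        pixel_size_um=px,
        rp_um=spec.rp,
        rp_err_um=0.05,
        mouth_x_px=mouth_x,
        axis_y_px=axis_y,
        roi_px=(roi[0], roi[1], roi[2], roi[3]),
    )
    return AspirationSeries(spec=spec, steps=tuple(steps), config=config)


@dataclass(frozen=True)
class BilayerSimSpec:
    """Study conditions for synthetic bilayer frames (lengths in nm).

    Defaults mirror the simulated systems: 324 lipids per leaflet and, when
    oil is present, on the order of 100 octane molecules in the core.
    """

    n_per_leaflet: int = 324
    hpp_true: float = 3.83
    z_sigma: float = 0.3
    chain_overlap: float = 1.0
    n_octane: int = 0
    box_xy: float = 15.0
    n_frames: int = 20
    seed: int = 0
    octane_sigma: float = 0.35

    def __post_init__(self) -> None:
        if self.n_per_leaflet < 1:
            raise ValueError("n_per_leaflet must be >= 1")
        if self.hpp_true <= 0:
            raise ValueError("hpp_true must be positive")
        if self.z_sigma < 0 or self.n_octane < 0:
            raise ValueError("z_sigma and n_octane must be non-negative")
        if self.chain_overlap > self.hpp_true:
            raise ValueError("unphysical: chain_overlap exceeds hpp_true")
        if self.chain_overlap < 0:
            raise ValueError("chain_overlap must be non-negative")


def gen_bilayer_frames(spec: BilayerSimSpec) -> list[BilayerFrame]:
    """Synthetic bilayer frames with prescribed h_pp and leaflet overlap.

    Phosphorus atoms sit at z = +/- hpp_true/2 with Normal(0, z_sigma)
    jitter; each lipid contributes 16 chain pseudo-atoms drawn uniformly
    between its phosphorus plane and the far edge of the overlap region, so
    the two leaflets' chain mass distributions overlap over exactly
    ``chain_overlap`` nm; octane pseudo-atoms are centred at the midplane.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_leaflet
    nc = n * CHAIN_ATOMS_PER_LIPID
    half_h = spec.hpp_true / 2.0
    half_c = spec.chain_overlap / 2.0
    lz = max(2.0 * (half_h + 5.0 * spec.z_sigma) + 2.0, 8.0)
    box = (spec.box_xy, spec.box_xy, lz)

    frames = []
    for _ in range(spec.n_frames):
        parts = []
        for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
            zp = sign * half_h + rng.normal(0.0, spec.z_sigma, n)
            lo, hi = (-half_c, half_h) if sign > 0 else (-half_h, half_c)
            zc = rng.uniform(lo, hi, nc)
            z = np.concatenate([zp, zc])
            xy = rng.uniform(0.0, spec.box_xy, (n + nc, 2))
            parts.append(
                dict(
                    coords=np.column_stack([xy, z]),
                    mass=np.concatenate(
                        [np.full(n, PHOSPHORUS_MASS), np.full(nc, CHAIN_PSEUDOATOM_MASS)]
                    ),
                    species=np.array(["lipid"] * (n + nc)),
                    leaflet=np.array([leaflet] * (n + nc)),
                    element=np.array(["P"] * n + ["C"] * nc),
                )
            )
        if spec.n_octane:
            no = spec.n_octane
            z = rng.normal(0.0, spec.octane_sigma, no)
            xy = rng.uniform(0.0, spec.box_xy, (no, 2))
            parts.append(
                dict(
                    coords=np.column_stack([xy, z]),
                    mass=np.full(no, OCTANE_MASS),
                    species=np.array(["octane"] * no),
                    leaflet=np.array(["none"] * no),
                    element=np.array(["C"] * no),
                )
            )
        frames.append(
            BilayerFrame(
                coords=np.concatenate([p["coords"] for p in parts]),
                mass=np.concatenate([p["mass"] for p in parts]),
                species=np.concatenate([p["species"] for p in parts]),
                leaflet=np.concatenate([p["leaflet"] for p in parts]),
                element=np.concatenate([p["element"] for p in parts]),
                box=box,
            )
        )
    return frames


def gen_area_series(
    mean_area: float,
    ka_true: float,
    temperature: float,
    n_frames: int,
    seed: int = 0,
) -> np.ndarray:
    """Equilibrium box-area series (nm^2) with Var(A) = kB*T*<A>/K_A."""
    if ka_true <= 0:
        raise ValueError("ka_true must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    var = _KB * temperature * mean_area / ka_true * 1e21  # nm^4 (K_A in mN/m)
    rng = np.random.default_rng(seed)
    return rng.normal(mean_area, math.sqrt(var), n_frames)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mean: float
    sd: float
    n: int
    error_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class PopulationSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


def gen_population(spec: PopulationSpec) -> pd.DataFrame:
    """Per-vesicle measurement table: columns (group, value, error)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        values = rng.normal(g.mean, g.sd, g.n)
        for v in values:
            rows.append({"group": g.label, "value": float(v), "error": g.error_scale})
    return pd.DataFrame(rows, columns=["group", "value", "error"])
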