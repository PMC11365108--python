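"""Bilayer trajectory metrics: thickness, density profiles, interdigitation, K_A.

Frames carry explicitly tagged atoms (leaflet membership from the input, not
from the sign of z) and an orthorhombic box.  All metrics re-reference z to
the lipid centre of mass (circular mean over the periodic box), so they are
invariant under rigid z-translation of the input frames.

Quantities:

* ``thickness_pp`` — bilayer thickness h_pp, the difference between the mean
  heights of the phosphorus atoms of the two leaflets.
* ``density_profile`` — mass density along the membrane normal,
  histogram mass / (Lx * Ly * bin_width), averaged over frames.
* ``interdigitation`` — overlap width of the two leaflets' mass
  distributions, w = integral of 4*rho_u*rho_l / (rho_u + rho_l)^2 dz; for a
  region where both leaflets contribute equally the integrand is 1, so w is
  the length of the shared support.
* ``ka_from_area_fluctuations`` — equilibrium box-area fluctuation estimator
  K_A = kB * T * <A> / Var(A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.constants import k as _KB  # J/K

from .exceptions import AnalysisError

__all__ = [
    "BilayerFrame",
    "DensityProfile",
    "ThicknessResult",
    "InterdigitationResult",
    "thickness_pp",
    "density_profile",
    "interdigitation",
    "overlap_width",
    "ka_from_area_fluctuations",
    "count_acyl_maxima",
]


@dataclass
class BilayerFrame:
    """Tagged atom coordinates (nm) plus an orthorhombic box (Lx, Ly, Lz nm)."""

    coords: np.ndarray          # (n, 3) nm
    mass: np.ndarray            # (n,) amu
    species: np.ndarray         # (n,) str in {lipid, octane, water, ion}
    leaflet: np.ndarray         # (n,) str in {upper, lower, none}
    element: np.ndarray         # (n,) str
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if min(self.box) <= 0:
            raise ValueError("box edges must be positive")
        n = self.coords.shape[0]
        for name in ("mass", "species", "leaflet", "element"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords")

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def total_mass(self) -> float:
        return float(self.mass.sum())


def _select(frame: BilayerFrame, selection) -> np.ndarray:
    if callable(selection):
        mask = np.asarray(selection(frame), dtype=bool)
    elif selection == "all":
        mask = np.ones(len(frame.mass), dtype=bool)
    elif selection in ("lipid", "octane", "water", "ion"):
        mask = frame.species == selection
    elif selection == "phosphorus":
        mask = (frame.species == "lipid") & (frame.element == "P")
    elif selection == "chains":
        mask = (frame.species == "lipid") & (frame.element != "P")
    elif selection in ("upper", "lower"):
        mask = (frame.species == "lipid") & (frame.leaflet == selection)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return mask


def _recentered_z(frame: BilayerFrame) -> np.ndarray:
    """z wrapped into the box and referenced to the lipid circular mean."""
    lz = frame.box[2]
    z = np.mod(frame.z, lz)
    lipid = frame.species == "lipid"
    if not lipid.any():
        lipid = np.ones_like(lipid)
    theta = 2.0 * np.pi * z[lipid] / lz
    w = frame.mass[lipid]
    zc = lz / (2.0 * np.pi) * math.atan2(
        float(np.sum(w * np.sin(theta))), float(np.sum(w * np.cos(theta)))
    )
    zr = z - zc
    return np.mod(zr + lz / 2.0, lz) - lz / 2.0


@dataclass(frozen=True)
class ThicknessResult:
    h_pp: float
    sem: float
    n_frames: int


def thickness_pp(frames: Sequence[BilayerFrame]) -> ThicknessResult:
    """Phosphorus-plane separation h_pp (nm), mean and SEM over frames."""
    values = []
    for i, frame in enumerate(frames):
        z = _recentered_z(frame)
        p = _select(frame, "phosphorus")
        up = p & (frame.leaflet == "upper")
        lo = p & (frame.leaflet == "lower")
        if not up.any() or not lo.any():
            raise AnalysisError(f"frame {i}: missing phosphorus atoms in a leaflet")
        values.append(float(z[up].mean() - z[lo].mean()))
    values = np.array(values)
    n = len(values)
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ThicknessResult(h_pp=float(values.mean()), sem=sem, n_frames=n)


@dataclass(frozen=True)
class DensityProfile:
    z: np.ndarray          # bin centers, nm
    density: np.ndarray    # amu / nm^3
    bin_width: float

    def total_mass(self, lateral_area: float) -> float:
        """Mass implied by the profile for a given Lx*Ly (nm^2)."""
        return float(self.density.sum() * lateral_area * self.bin_width)


def _common_edges(frames, bin_width):
    zmin = math.inf
    zmax = -math.inf
    for frame in frames:
        z = _recentered_z(frame)
        zmin = min(zmin, float(z.min()))
        zmax = max(zmax, float(z.max()))
    lo = math.floor(zmin / bin_width) - 1
    hi = math.ceil(zmax / bin_width) + 1
    return np.arange(lo, hi + 1) * bin_width


def density_profile(
    frames: Sequence[BilayerFrame],
    selection="all",
    bin_width: float = 0.1,
) -> DensityProfile:
    """Mass-density profile along the membrane normal, averaged over frames."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = list(frames)
    if not frames:
        raise AnalysisError("no frames")
    edges = _common_edges(frames, bin_width)
    acc = np.zeros(edges.size - 1)
    any_atoms = False
    for frame in frames:
        mask = _select(frame, selection)
        if not mask.any():
            continue
        any_atoms = True
        z = _recentered_z(frame)[mask]
        hist, _ = np.histogram(z, bins=edges, weights=frame.mass[mask])
        acc += hist / (frame.box[0] * frame.box[1] * bin_width)
    if not any_atoms:
        raise AnalysisError(f"empty selection {selection!r}")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z=centers, density=acc / len(frames), bin_width=bin_width)


@dataclass(frozen=True)
class InterdigitationResult:
    width: float
    bin_width: float


def overlap_width(z: np.ndarray, rho_u: np.ndarray, rho_l: np.ndarray) -> float:
    """Trapezoid integral of 4*rho_u*rho_l/(rho_u+rho_l)^2 over the support."""
    rho_u = np.asarray(rho_u, dtype=np.float64)
    rho_l = np.asarray(rho_l, dtype=np.float64)
    total = rho_u + rho_l
    g = np.zeros_like(total)
    pos = total > 0
    g[pos] = 4.0 * rho_u[pos] * rho_l[pos] / total[pos] ** 2
    return float(np.trapezoid(g, np.asarray(z, dtype=np.float64)))


def interdigitation(
    frames: Sequence[BilayerFrame],
    bin_width: float = 0.1,
) -> InterdigitationResult:
    """Leaflet interdigitation width (nm) from lipid mass-density overlap."""
    frames = list(frames)
    if not frames:
        raise AnalysisError("no frames")
    for i, frame in enumerate(frames):
        if not _select(frame, "upper").any() or not _select(frame, "lower").any():
            raise AnalysisError(f"frame {i}: a leaflet selection is empty")
    up = density_profile(frames, "upper", bin_width)
    lo = density_profile(frames, "lower", bin_width)
    return InterdigitationResult(
        width=overlap_width(up.z, up.density, lo.density), bin_width=bin_width
    )


def ka_from_area_fluctuations(areas, temperature: float) -> float:
    """Area compressibility modulus (mN/m) from box-area fluctuations.

    K_A = kB * T * <A> / Var(A), with areas in nm^2 and unbiased sample
    variance.  Valid for equilibrium NPT/NPgammaT area time series.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size < 10:
        raise AnalysisError("need at least 10 area samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    var = float(areas.var(ddof=1))
    if var == 0.0:
        raise AnalysisError("zero area variance: K_A undefined")
    mean = float(areas.mean())
    # J * nm^2 / nm^4 = J/nm^2; 1 J/nm^2 = 1e18 N/m = 1e21 mN/m
    return _KB * temperature * mean / var * 1e21


def count_acyl_maxima(profile: DensityProfile, smoothing_window: int = 5) -> int:
    """Number of strict local maxima of the smoothed density profile."""
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    d = np.asarray(profile.density, dtype=np.float64)
    if d.size == 0:
        raise AnalysisError("empty profile")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        d = np.convolve(d, kernel, mode="same")
    interior = d[1:-1]
    return int(np.sum((interior > d[:-2]) & (interior > d[2:])))
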