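"""End-to-end aspiration analysis: image series -> geometry -> K_A."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import AnalysisError
from .imaging import (
    RegionOfInterest,
    VesicleGeometry,
    estimate_line_spread,
    estimate_vesicle_radius,
    measure_projection_length,
)
from .mechanics import (
    ElasticityFitResults,
    PressureStep,
    TensionAreaPoint,
    analyze_series,
    fit_ka,
)

__all__ = ["AnalysisConfig", "measure_frames", "analyze_aspiration", "AspirationAnalysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Per-series analysis configuration (one ROI for the whole series)."""

    pixel_size_um: float
    rp_um: float
    rp_err_um: float
    mouth_x_px: float
    axis_y_px: float
    roi_px: tuple[int, int, int, int]  # x0, y0, x1, y1
    tau_min: float = 0.5

    @property
    def roi(self) -> RegionOfInterest:
        x0, y0, x1, y1 = self.roi_px
        return RegionOfInterest(x0, y0, x1, y1, self.mouth_x_px, self.axis_y_px)

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "rp_um": self.rp_um,
            "rp_err_um": self.rp_err_um,
            "mouth_x_px": self.mouth_x_px,
            "axis_y_px": self.axis_y_px,
            "roi_px": list(self.roi_px),
            "tau_min": self.tau_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(
            pixel_size_um=float(d["pixel_size_um"]),
            rp_um=float(d["rp_um"]),
            rp_err_um=float(d.get("rp_err_um", 0.0)),
            mouth_x_px=float(d["mouth_x_px"]),
            axis_y_px=float(d["axis_y_px"]),
            roi_px=tuple(int(v) for v in d["roi_px"]),
            tau_min=float(d.get("tau_min", 0.5)),
        )


def measure_frames(images: Sequence, config: AnalysisConfig) -> list[VesicleGeometry]:
    """Per-frame vesicle geometry (Rv, Lp) from an aspiration image series."""
    roi = config.roi
    geoms = []
    for image in images:
        rv, rv_err, diag = estimate_vesicle_radius(image, roi, config.pixel_size_um)
        try:
            # self-calibrate the membrane line spread from the vesicle ring;
            # it anchors the tongue-tip edge fit on the same frame
            sigma = estimate_line_spread(image, diag.fits[1], roi)
        except AnalysisError:
            sigma = None
        lp, lp_err = measure_projection_length(
            image, None, config.pixel_size_um, config.rp_um,
            mouth_x=config.mouth_x_px, axis_y=config.axis_y_px,
            ring_sigma=sigma,
        )
        geoms.append(
            VesicleGeometry(
                rp=config.rp_um, rv=rv, lp=lp,
                rp_err=config.rp_err_um, rv_err=rv_err, lp_err=lp_err,
            )
        )
    return geoms


@dataclass(frozen=True)
class AspirationAnalysis:
    geometries: list[VesicleGeometry]
    points: list[TensionAreaPoint]
    fit: ElasticityFitResults = field(repr=False)


def analyze_aspiration(
    images: Sequence,
    pressures: Sequence[PressureStep],
    config: AnalysisConfig,
) -> AspirationAnalysis:
    """Full chain: measure every frame, build tension-area points, fit K_A."""
    geoms = measure_frames(images, config)
    points = analyze_series(geoms, list(pressures))
    fit = fit_ka(points, tau_min=config.tau_min)
    return AspirationAnalysis(geometries=geoms, points=points, fit=fit)
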