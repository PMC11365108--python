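"""Exception hierarchy for guvmech."""


class GuvmechError(Exception):
    """Base class for all guvmech errors."""


class DegenerateCircleError(GuvmechError):
    """Circle fit attempted on a collinear or otherwise degenerate point set."""


class GeometryError(GuvmechError):
    """A vesicle geometry violates the aspiration-regime preconditions."""


class GeometryInfeasibleError(GeometryError):
    """No aspirated-vesicle geometry realises the requested (area, volume, Rp)."""


class CanvasOverflowError(GuvmechError):
    """Rendered contour does not fit on the requested image canvas."""


class TongueNotFoundError(GuvmechError):
    """No aspirated tongue detected in the pipette band."""


class AnalysisError(GuvmechError):
    """Generic failure of an analysis stage (too few points, empty masks, ...)."""
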