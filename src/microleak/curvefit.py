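"""Interface curve fitting and calibrated dye-penetration measurement.

The dye path along the die--cement interface is modelled by a 4th-order
polynomial

    y = a*x**4 + b*x**3 + c*x**2 + d*x + e

fitted by least squares to the marker trace, and the penetration distance
is the arc length of the fitted curve,

    s = integral over [x_lo, x_hi] of sqrt(1 + (dy/dx)**2) dx,

evaluated by adaptive quadrature and converted to millimetres with the
microscope calibration factor (default 0.0013028 mm/pixel).  Dye that
reaches the die-centre landmark, or whose converted length reaches the
complete-penetration distance, is assigned the cap (default 7.18 mm,
margin to die centre) exactly.

Fitting happens in a rotation-stabilised local frame: the markers'
principal axis is the abscissa, so near-vertical interfaces in image
coordinates remain single-valued functions.  Arc length is invariant
under this rigid re-framing, so the measured distance is unchanged for
any interface that is single-valued in image coordinates too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .segmentation import MarkerTrace

__all__ = [
    "Frame",
    "FittedCurve",
    "CalibrationSpec",
    "PenetrationResult",
    "UnfittableTraceError",
    "fit_interface_curve",
    "arc_length",
    "measure_penetration",
    "render_overlay",
]

OVERLAY_COLOR = (255, 0, 0)

#: penetration-measurement outcome labels
STATUS_MEASURED = "measured"
STATUS_COMPLETE = "complete_penetration"
STATUS_NO_DYE = "no_dye"
STATUS_DELAMINATED = "delaminated"


class UnfittableTraceError(ValueError):
    """Raised when a trace has fewer than two markers."""


@dataclass(frozen=True)
class Frame:
    """Rigid map between image pixel coordinates and the curve's local frame.

    ``angle`` is the rotation of the local abscissa measured in math
    coordinates (x = column, y = row), ``origin`` the math-coordinate
    translation.  Local coordinates of an image point p are its components
    along the rotated basis (u, v) after subtracting the origin.
    """

    angle: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def u(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])

    @property
    def v(self) -> np.ndarray:
        return np.array([-math.sin(self.angle), math.cos(self.angle)])

    def to_local(self, points_rowcol: np.ndarray) -> np.ndarray:
        """Map (n, 2) image (row, col) points to (n, 2) local (x, y)."""
        p = np.atleast_2d(np.asarray(points_rowcol, dtype=float))
        xy = np.column_stack([p[:, 1], p[:, 0]]) - np.asarray(self.origin)
        return np.column_stack([xy @ self.u, xy @ self.v])

    def to_image(self, x, y) -> np.ndarray:
        """Map local (x, y) to (n, 2) image (row, col) points."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        xy = np.asarray(self.origin) + np.outer(x, self.u) + np.outer(y, self.v)
        return np.column_stack([xy[:, 1], xy[:, 0]])


@dataclass
class FittedCurve:
    """A polynomial interface model in its local frame.

    ``coef`` holds ascending-power coefficients (c0 ... c_deg); the
    ``coefficients`` property exposes them as the quartic constants
    (a, b, c, d, e), highest power first, zero-padded when the fitted
    degree is below 4.
    """

    coef: np.ndarray
    frame: Frame
    x_lo: float
    x_hi: float
    degree_used: int

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)

    @classmethod
    def from_polynomial(
        cls,
        coefficients,
        x_lo: float,
        x_hi: float,
        angle: float = 0.0,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "FittedCurve":
        """Build a curve from (a, b, c, d, e)-style descending coefficients."""
        asc = np.asarray(coefficients, dtype=float)[::-1]
        return cls(asc, Frame(angle, origin), float(x_lo), float(x_hi), len(asc) - 1)

    @property
    def coefficients(self) -> tuple[float, float, float, float, float]:
        padded = np.zeros(5)
        padded[: len(self.coef)] = self.coef
        a, b, c, d, e = padded[::-1]
        return (a, b, c, d, e)

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(x, self.coef)

    def slope(self, x):
        return np.polynomial.polynomial.polyval(
            x, np.polynomial.polynomial.polyder(self.coef)
        )

    def point_at(self, x) -> np.ndarray:
        """Image-coordinate (row, col) point(s) on the curve."""
        return self.frame.to_image(x, self(x))

    def normal_at(self, x: float) -> np.ndarray:
        """Unit normal (d_row, d_col) to the curve at local abscissa x."""
        m = float(self.slope(x))
        tangent_local = np.array([1.0, m]) / math.hypot(1.0, m)
        normal_local = np.array([-tangent_local[1], tangent_local[0]])
        n_math = normal_local[0] * self.frame.u + normal_local[1] * self.frame.v
        return np.array([n_math[1], n_math[0]])  # (row, col)


@dataclass(frozen=True)
class CalibrationSpec:
    """Spatial calibration and complete-penetration cap.

    mm_per_pixel : graticule-derived conversion factor (default 0.0013028).
    cap_mm : margin-to-die-centre distance assigned on complete
        penetration (default 7.18 mm).
    """

    mm_per_pixel: float = 0.0013028
    cap_mm: float = 7.18

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.cap_mm <= 0:
            raise ValueError("cap_mm must be positive")


@dataclass
class PenetrationResult:
    arc_length_px: float
    penetration_mm: float
    capped: bool
    status: str
    degree_used: int = 4


def fit_interface_curve(
    trace: MarkerTrace | np.ndarray,
    degree: int = 4,
    frame: str = "auto",
) -> FittedCurve:
    """Least-squares polynomial fit of degree min(degree, n-1) to a trace.

    Parameters
    ----------
    trace : marker trace or bare (n, 2) array of (row, col) points.
    degree : requested polynomial degree (the interface model is quartic).
    frame : ``"auto"`` fits in the markers' principal-axis frame, oriented
        from the first (margin-end) marker inward; ``"image"`` fits
        y = f(x) directly in image coordinates (x = column, y = row).
    """
    points = trace.markers if isinstance(trace, MarkerTrace) else np.asarray(trace)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n < 2:
        raise UnfittableTraceError(f"need >= 2 markers to fit a curve, got {n}")
    if frame not in ("auto", "image"):
        raise ValueError(f"frame must be 'auto' or 'image', got {frame!r}")

    if frame == "image":
        local_frame = Frame()
    else:
        math_pts = np.column_stack([points[:, 1], points[:, 0]])
        centered = math_pts - math_pts.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        u = v[:, np.argmax(w)]
        if (math_pts[-1] - math_pts[0]) @ u < 0:
            u = -u  # margin-end marker at the low-x side
        local_frame = Frame(math.atan2(u[1], u[0]), tuple(math_pts.mean(axis=0)))

    local = local_frame.to_local(points)
    xl, yl = local[:, 0], local[:, 1]
    deg = min(degree, n - 1)
    poly = np.polynomial.Polynomial.fit(xl, yl, deg).convert()
    coef = np.zeros(deg + 1)
    coef[: len(poly.coef)] = poly.coef
    return FittedCurve(coef, local_frame, float(xl.min()), float(xl.max()), deg)


def arc_length(
    curve: FittedCurve, x_lo: float | None = None, x_hi: float | None = None
) -> float:
    """Arc length of the fitted polynomial over [x_lo, x_hi], in pixels.

    Adaptive quadrature of sqrt(1 + f'(x)^2) to relative tolerance 1e-8.
    Bounds default to the curve's fit bounds.
    """
    x_lo = curve.x_lo if x_lo is None else float(x_lo)
    x_hi = curve.x_hi if x_hi is None else float(x_hi)
    if x_lo > x_hi:
        raise ValueError(f"x_lo={x_lo} > x_hi={x_hi}")
    der = np.polynomial.polynomial.polyder(curve.coef)

    def integrand(x):
        dy = np.polynomial.polynomial.polyval(x, der)
        return np.sqrt(1.0 + dy * dy)

    value, _ = quad(integrand, x_lo, x_hi, epsabs=0.0, epsrel=1e-8, limit=200)
    return float(value)


def measure_penetration(
    trace: MarkerTrace | None,
    calibration: CalibrationSpec | None = None,
    die_center: tuple[float, float] | None = None,
    degree: int = 4,
) -> PenetrationResult:
    """Measure calibrated dye penetration from a marker trace.

    An empty (or single-marker, hence unfittable) trace reports
    ``no_dye`` with 0 mm.  Otherwise the quartic is fitted, integrated
    over the dye extent, and converted with ``mm_per_pixel``.  The result
    is capped at ``cap_mm`` exactly when the trace reaches or passes the
    die-centre landmark, or when the converted length reaches the cap.

    The integration bounds cover the dye pixels' full projection span
    when the trace records it (bin centroids alone under-reach the dye
    front by half a bin at each end).
    """
    calibration = calibration or CalibrationSpec()
    if trace is None or trace.is_empty:
        return PenetrationResult(0.0, 0.0, False, STATUS_NO_DYE, 0)
    try:
        curve = fit_interface_curve(trace, degree=degree)
    except UnfittableTraceError:
        return PenetrationResult(0.0, 0.0, False, STATUS_NO_DYE, 0)

    x_lo, x_hi = curve.x_lo, curve.x_hi
    span = getattr(trace, "span_px", 0.0) or 0.0
    if span > (x_hi - x_lo):
        pad = 0.5 * (span - (x_hi - x_lo))
        x_lo, x_hi = x_lo - pad, x_hi + pad

    s = arc_length(curve, x_lo, x_hi)
    mm = s * calibration.mm_per_pixel

    capped = mm >= calibration.cap_mm
    if die_center is not None:
        t_center = curve.frame.to_local(np.asarray(die_center, float))[0, 0]
        if x_hi >= t_center:  # far end of the trace at/past the centre
            capped = True
    if capped:
        return PenetrationResult(
            s, calibration.cap_mm, True, STATUS_COMPLETE, curve.degree_used
        )
    return PenetrationResult(s, mm, False, STATUS_MEASURED, curve.degree_used)


def render_overlay(
    image: np.ndarray,
    curve: FittedCurve,
    color: tuple[int, int, int] = OVERLAY_COLOR,
) -> np.ndarray:
    """Copy of ``image`` with the fitted curve rasterized for visual check."""
    out = np.asarray(image, dtype=np.uint8).copy()
    n = max(2, int(4 * (curve.x_hi - curve.x_lo)) + 1)
    xs = np.linspace(curve.x_lo, curve.x_hi, n)
    pts = curve.point_at(xs)
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, out.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, out.shape[1] - 1)
    out[rows, cols] = color
    return out
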