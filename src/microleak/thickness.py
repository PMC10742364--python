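"""Cement-layer thickness between the die and restoration interfaces.

Thickness is sampled at stations spaced evenly *in arc length* along the
die-side interface, from its margin end to its far (occlusal-middle) end,
matching how penetration itself is measured.  At each station the
thickness is the distance from the die-curve point, along the die curve's
local normal, to the cement--restoration interface, converted to
micrometres.  A station whose normal ray misses the restoration curve
within its fitted extent is flagged missing, excluded from the summary,
and reported with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .curvefit import CalibrationSpec, FittedCurve, arc_length

__all__ = ["ThicknessResult", "measure_cement_thickness"]


@dataclass
class ThicknessResult:
    """Per-station cement thickness, in micrometres."""

    station_thickness_um: list[float]
    mean_um: float
    sd_um: float
    n_stations: int
    missing_stations: list[int] = field(default_factory=list)


def _station_abscissae(curve: FittedCurve, n_stations: int) -> np.ndarray:
    """Local abscissae at evenly spaced arc-length fractions, endpoints inclusive."""
    total = arc_length(curve)
    if n_stations == 1:
        fractions = np.array([0.5])
    else:
        fractions = np.linspace(0.0, 1.0, n_stations)
    xs = []
    for f in fractions:
        target = f * total
        if target <= 0.0:
            xs.append(curve.x_lo)
        elif target >= total:
            xs.append(curve.x_hi)
        else:
            xs.append(
                brentq(
                    lambda x: arc_length(curve, curve.x_lo, x) - target,
                    curve.x_lo,
                    curve.x_hi,
                    xtol=1e-9,
                )
            )
    return np.asarray(xs)


def _normal_ray_gap(
    die_curve: FittedCurve, resto_curve: FittedCurve, x_station: float
) -> float | None:
    """Distance (px) from the die curve along its normal to the resto curve.

    The restoration curve point P(u) hit by the ray satisfies
    cross(P(u) - Q, n) = 0; roots are bracketed on a dense scan of the
    restoration curve's extent (slightly extended so stations at the
    margins still intersect) and the nearest intersection is kept.
    """
    q = die_curve.point_at(x_station)[0]  # (row, col)
    n = die_curve.normal_at(x_station)

    pad = 0.05 * (resto_curve.x_hi - resto_curve.x_lo) + 1.0
    us = np.linspace(resto_curve.x_lo - pad, resto_curve.x_hi + pad, 512)
    pts = resto_curve.point_at(us)
    dr, dc = pts[:, 0] - q[0], pts[:, 1] - q[1]
    cross = dr * n[1] - dc * n[0]

    best: float | None = None
    for i in np.flatnonzero(np.sign(cross[:-1]) * np.sign(cross[1:]) <= 0):
        if cross[i] == 0.0 and cross[i + 1] == 0.0:
            continue
        f = lambda u: (
            (resto_curve.point_at(u)[0][0] - q[0]) * n[1]
            - (resto_curve.point_at(u)[0][1] - q[1]) * n[0]
        )
        try:
            u_hit = brentq(f, us[i], us[i + 1], xtol=1e-9)
        except ValueError:
            continue
        p = resto_curve.point_at(u_hit)[0]
        d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
        if best is None or d < best:
            best = d
    return best


def measure_cement_thickness(
    die_curve: FittedCurve,
    resto_curve: FittedCurve,
    calibration: CalibrationSpec | None = None,
    n_stations: int = 3,
) -> ThicknessResult:
    """Measure cement thickness at evenly spaced stations along the die curve.

    Stations are placed at arc-length fractions 0, 1/(n-1), ..., 1 along
    the die-side interface (margin, ..., occlusal middle; default three
    stations).  Thickness at each station is the normal-ray distance to
    the restoration curve in micrometres.
    """
    calibration = calibration or CalibrationSpec()
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    um_per_px = calibration.mm_per_pixel * 1000.0

    values: list[float] = []
    missing: list[int] = []
    for i, x in enumerate(_station_abscissae(die_curve, n_stations)):
        gap_px = _normal_ray_gap(die_curve, resto_curve, float(x))
        if gap_px is None:
            missing.append(i)
            warnings.warn(
                f"thickness station {i}: normal ray misses the restoration "
                "interface; station excluded",
                stacklevel=2,
            )
        else:
            values.append(gap_px * um_per_px)

    arr = np.asarray(values)
    mean = float(arr.mean()) if len(arr) else float("nan")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0 if len(arr) == 1 else float("nan")
    return ThicknessResult(values, mean, sd, n_stations, missing)
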