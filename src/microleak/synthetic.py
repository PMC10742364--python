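"""Synthetic cross-section scenes with analytically known ground truth.

No specimen images from the original microleakage experiments were ever
deposited, so every other module is validated against generated scenes: a
die region, a cement band of configurable thickness profile, a
restoration region with a smooth or stepped ("staircase", emulating the
layer lines of additively manufactured fitting surfaces) interface, and a
dye band painted along the die--cement interface up to an exactly known
arc length.

The generator carries its own arc-length oracle (composite Gauss--Legendre
quadrature, independent of the adaptive quadrature used by the
measurement path) so that ground truth and measurement can be compared as
two independent computations.

Scene geometry: the die--cement interface is row = p(col) for a
polynomial p of degree <= 4 (ascending coefficients, scene coordinates
x = column, y = row, origin top-left).  The die lies below the interface,
the cement band above it, and the restoration above the cement.  The dye
band sits on the cement side of the interface, starting at the margin
(column 0) and ending where the interface arc length reaches
``dye_extent_px``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .segmentation import DyeThreshold, save_image
from .stats import GroupStudy

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "GroupParams",
    "polynomial_arc_length",
    "generate_cross_section",
    "generate_group_study",
    "write_fixture",
]

# default region colours: dye inside the printed threshold box, the rest outside
DYE_COLOR = (60, 60, 175)
DIE_COLOR = (230, 230, 230)
CEMENT_COLOR = (200, 190, 160)
RESTO_COLOR = (240, 225, 210)


@dataclass
class SceneSpec:
    """Parameters of one synthetic cross-section scene.

    ``die_curve_coeffs`` are ascending-power coefficients of the
    die--cement interface row = p(col).  ``cement_gap_um`` is the
    (start, end) cement thickness in micrometres, interpolated linearly
    across the image width (equal values give a constant band).
    ``dye_extent_px`` is the ground-truth arc length of the dye front
    along the interface, in pixels.
    """

    image_size: tuple[int, int] = (480, 720)
    die_curve_coeffs: tuple[float, ...] = (320.0, -0.05, 1.0e-4)
    cement_gap_um: tuple[float, float] = (100.0, 100.0)
    dye_extent_px: float = 400.0
    dye_band_width: float = 3.0
    dye_color: tuple[int, int, int] = DYE_COLOR
    die_color: tuple[int, int, int] = DIE_COLOR
    cement_color: tuple[int, int, int] = CEMENT_COLOR
    resto_color: tuple[int, int, int] = RESTO_COLOR
    noise_sd: float = 0.0
    texture: str = "smooth"
    step_period: int = 12
    step_amplitude: float = 2.0
    mm_per_pixel: float = 0.0013028
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dye_extent_px < 0:
            raise ValueError("dye_extent_px must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture not in ("smooth", "stepped"):
            raise ValueError(f"texture must be 'smooth' or 'stepped', got {self.texture!r}")
        if len(self.die_curve_coeffs) > 5:
            raise ValueError("die interface polynomial degree must be <= 4")
        box = DyeThreshold()
        if not box.contains(self.dye_color):
            raise ValueError(f"dye_color {self.dye_color} outside the dye threshold box")
        for name in ("die_color", "cement_color", "resto_color"):
            if box.contains(getattr(self, name)):
                raise ValueError(f"{name} falls inside the dye threshold box")


@dataclass
class GroundTruth:
    """Analytic ground truth accompanying a generated scene."""

    true_arc_length_px: float
    true_penetration_mm: float
    true_thickness_um: list[float]
    curve_samples: np.ndarray
    margin_anchor: tuple[int, int]
    mm_per_pixel: float

    def to_json(self) -> str:
        d = asdict(self)
        d["curve_samples"] = np.asarray(self.curve_samples).tolist()
        return json.dumps(d, indent=1)


def polynomial_arc_length(
    coeffs_ascending, x0: float, x1: float, order: int = 32, pieces: int = 16
) -> float:
    """Arc length of y = p(x) over [x0, x1] by composite Gauss-Legendre.

    This is the generator's independent oracle; fixed-order product
    quadrature on a smooth quartic integrand is exact to machine noise at
    these settings.
    """
    if x1 < x0:
        raise ValueError("x1 < x0")
    der = np.polynomial.polynomial.polyder(np.asarray(coeffs_ascending, float))
    nodes, weights = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(x0, x1, pieces + 1)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        dy = np.polynomial.polynomial.polyval(mid + half * nodes, der)
        total += half * float(np.sum(weights * np.sqrt(1.0 + dy * dy)))
    return total


def _invert_arc_length(coeffs, target: float, x_max: float) -> float:
    """x such that the interface arc length over [0, x] equals ``target``."""
    lo, hi = 0.0, x_max
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if polynomial_arc_length(coeffs, 0.0, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _normal_gap_px(coeffs, x_station: float, gap_of_x) -> float:
    """Normal-ray distance from the die interface to the offset curve r(x).

    r(x) = p(x) - gap_of_x(x) is sampled densely as a polyline and the
    intersection with the die-normal ray located by a linear crossing of
    the cross product (independent of the measurement module's
    root-finding on fitted polynomials).
    """
    coeffs = np.asarray(coeffs, float)
    der = np.polynomial.polynomial.polyder(coeffs)
    y_s = np.polynomial.polynomial.polyval(x_station, coeffs)
    m = np.polynomial.polynomial.polyval(x_station, der)
    # unit normal in (x, y): perpendicular to tangent (1, m)
    n = np.array([-m, 1.0]) / np.hypot(1.0, m)

    xs = np.linspace(x_station - 400.0, x_station + 400.0, 8001)
    rs = np.polynomial.polynomial.polyval(xs, coeffs) - gap_of_x(xs)
    cross = (xs - x_station) * n[1] - (rs - y_s) * n[0]
    sign_change = np.flatnonzero(np.sign(cross[:-1]) * np.sign(cross[1:]) <= 0)
    best = np.inf
    for i in sign_change:
        c0, c1 = cross[i], cross[i + 1]
        frac = 0.5 if c1 == c0 else -c0 / (c1 - c0)
        xh = xs[i] + frac * (xs[i + 1] - xs[i])
        yh = rs[i] + frac * (rs[i + 1] - rs[i])
        d = float(np.hypot(xh - x_station, yh - y_s))
        best = min(best, d)
    return best


def generate_cross_section(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a cross-section scene and return it with its ground truth.

    Deterministic for a fixed seed.  Raises if ``dye_extent_px`` exceeds
    the total interface arc length across the image.
    """
    h, w = spec.image_size
    coeffs = np.asarray(spec.die_curve_coeffs, float)
    x = np.arange(w, dtype=float)
    p = np.polynomial.polynomial.polyval(x, coeffs)  # die interface row

    um_per_px = spec.mm_per_pixel * 1000.0
    g0, g1 = spec.cement_gap_um
    gap_um = g0 + (g1 - g0) * x / max(w - 1, 1)
    gap_px = gap_um / um_per_px
    resto_boundary = p - gap_px
    if spec.texture == "stepped":
        wave = ((x.astype(int) // spec.step_period) % 2).astype(float)
        resto_boundary = resto_boundary - spec.step_amplitude * wave
    else:
        wave = np.zeros_like(x)

    rows = np.arange(h, dtype=float)[:, None]
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.cement_color
    img[rows >= p[None, :]] = spec.die_color
    img[rows < resto_boundary[None, :]] = spec.resto_color

    total_arc = polynomial_arc_length(coeffs, 0.0, float(w - 1))
    if spec.dye_extent_px > total_arc + 1e-9:
        raise ValueError(
            f"dye_extent_px={spec.dye_extent_px} exceeds interface arc "
            f"length {total_arc:.1f}"
        )
    if spec.dye_extent_px > 0:
        x_end = _invert_arc_length(coeffs, spec.dye_extent_px, float(w - 1))
        col_end = int(np.floor(x_end + 0.5))  # pixel whose centre is nearest
        band = spec.dye_band_width + spec.step_amplitude * wave * (
            spec.texture == "stepped"
        )
        dye = (
            (np.arange(w)[None, :] <= col_end)
            & (rows >= (p - band)[None, :])
            & (rows < p[None, :])
            & (rows >= resto_boundary[None, :])
        )
        img[dye] = spec.dye_color

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = img.astype(float) + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    # ground truth: thickness at three arc-length stations against the
    # smooth (nominal) gap profile, plus dense interface samples
    gap_of_x = lambda xs: (g0 + (g1 - g0) * xs / max(w - 1, 1)) / um_per_px
    stations = []
    for frac in (0.0, 0.5, 1.0):
        xs = _invert_arc_length(coeffs, frac * total_arc, float(w - 1))
        stations.append(_normal_gap_px(coeffs, xs, gap_of_x) * um_per_px)
    xs_dense = np.linspace(0.0, w - 1.0, 512)
    samples = np.column_stack(
        [np.polynomial.polynomial.polyval(xs_dense, coeffs), xs_dense]
    )
    anchor = (int(round(float(p[0]))), 0)
    truth = GroundTruth(
        true_arc_length_px=float(spec.dye_extent_px),
        true_penetration_mm=float(spec.dye_extent_px) * spec.mm_per_pixel,
        true_thickness_um=stations,
        curve_samples=samples,
        margin_anchor=anchor,
        mm_per_pixel=spec.mm_per_pixel,
    )
    return img, truth


@dataclass(frozen=True)
class GroupParams:
    """Penetration distribution of one specimen group.

    Penetration draws are normal(mean_mm, sd_mm) clipped to [0, cap_mm];
    each specimen independently delaminates with probability
    ``p_delaminated`` (delaminated specimens carry no measurement).
    """

    mean_mm: float
    sd_mm: float
    cap_mm: float = 7.18
    p_delaminated: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_mm < 0:
            raise ValueError("sd_mm must be >= 0")
        if self.cap_mm <= 0:
            raise ValueError("cap_mm must be positive")
        if not 0.0 <= self.p_delaminated <= 1.0:
            raise ValueError("p_delaminated must be in [0, 1]")


def generate_group_study(
    n_per_group: int,
    group_params: dict[str, GroupParams],
    seed: int = 0,
) -> GroupStudy:
    """Draw a capped-normal specimen study, deterministic per seed."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[float]] = {}
    delam: dict[str, int] = {}
    complete: dict[str, int] = {}
    for label, params in group_params.items():
        draws = rng.normal(params.mean_mm, params.sd_mm, n_per_group)
        delaminated = rng.random(n_per_group) < params.p_delaminated
        values = np.clip(draws, 0.0, params.cap_mm)[~delaminated]
        groups[label] = [float(v) for v in values]
        delam[label] = int(delaminated.sum())
        complete[label] = int(np.sum(values >= params.cap_mm))
    return GroupStudy(groups, delam, complete)


def write_fixture(
    out_dir: str | Path, name: str, image: np.ndarray, truth: GroundTruth
) -> tuple[Path, Path]:
    """Write a scene as PNG plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png = out_dir / f"{name}.png"
    sidecar = out_dir / f"{name}.truth.json"
    save_image(png, image)
    sidecar.write_text(truth.to_json())
    return png, sidecar
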