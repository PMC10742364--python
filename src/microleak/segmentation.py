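"""Dye segmentation and interface marker tracing.

A sectioned crown-on-die specimen image contains four optically distinct
regions: the zirconia die, the luting-cement band, the provisional
restoration, and (where microleakage occurred) methylene-blue dye that has
penetrated along the die--cement interface from the margin.  This module
turns such an image into

1. a boolean *dye mask* — pixels whose colour falls in a rectangular RGB
   box characteristic of the dye (default box: R <= 110, G <= 160,
   150 <= B <= 200), and
2. an ordered *marker trace* — one single-pixel marker per bin along the
   principal axis of the dye region, marking the path of the dye along the
   interface, ordered from the margin inward.

Marker placement is fully automated: a least-squares principal axis is put
through the dye pixels, the pixels are binned by their projection onto
that axis, and each occupied bin contributes the (rounded) centroid of its
dye pixels.  Images are plain ``(H, W, 3)`` uint8 arrays; :func:`load_image`
normalises PNG/TIFF input (alpha dropped, 16-bit rescaled to 8-bit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "DyeThreshold",
    "MarkerTrace",
    "EmptyImageError",
    "load_image",
    "save_image",
    "classify_dye_pixels",
    "extract_interface_markers",
    "render_markers",
]

MARKER_COLOR = (0, 255, 0)  # green single-pixel markers


class EmptyImageError(ValueError):
    """Raised when an image contains no pixels to classify."""


@dataclass(frozen=True)
class DyeThreshold:
    """Rectangular RGB box that classifies a pixel as penetrated dye.

    A pixel (R, G, B) is dye-positive iff
    ``R <= r_max and G <= g_max and b_min <= B <= b_max``.
    Defaults are the methylene-blue box (<=110, <=160, 150-200) on the
    8-bit scale.
    """

    r_max: int = 110
    g_max: int = 160
    b_min: int = 150
    b_max: int = 200

    def __post_init__(self) -> None:
        for name in ("r_max", "g_max", "b_min", "b_max"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.b_min > self.b_max:
            raise ValueError(f"b_min={self.b_min} > b_max={self.b_max}")

    def contains(self, rgb) -> bool:
        r, g, b = (int(c) for c in rgb)
        return r <= self.r_max and g <= self.g_max and self.b_min <= b <= self.b_max


@dataclass
class MarkerTrace:
    """Ordered single-pixel markers along the dye path at the interface.

    Attributes
    ----------
    markers : (n, 2) float array of (row, col) pixel coordinates, ordered
        starting from the end nearest the margin anchor.
    margin_anchor : (row, col) metadata landmark designating the margin end.
    axis : unit vector (d_row, d_col) of the dye region's principal axis,
        oriented from the margin inward (``None`` for empty/degenerate traces).
    span_px : extent of the dye pixels' projections onto the principal axis,
        in pixels.  Bin centroids sit half a bin inside the dye extent at
        each end; the penetration measurement uses this span to integrate
        over the full dye evidence.
    """

    markers: np.ndarray
    margin_anchor: tuple[float, float]
    axis: np.ndarray | None = None
    span_px: float = 0.0

    def __post_init__(self) -> None:
        self.markers = np.atleast_2d(np.asarray(self.markers, dtype=float))
        if self.markers.size == 0:
            self.markers = np.empty((0, 2), dtype=float)

    @property
    def is_empty(self) -> bool:
        return len(self.markers) == 0

    def __len__(self) -> int:
        return len(self.markers)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 RGB array.

    Grayscale input is replicated across channels, an alpha channel is
    dropped, and 16-bit input is rescaled to the 8-bit range (the dye
    threshold box is printed on the 8-bit scale).
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        arr = np.round(arr / 65535.0 * 255.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def _as_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise EmptyImageError("image contains no pixels")
    return arr


def classify_dye_pixels(
    image: np.ndarray, threshold: DyeThreshold | None = None
) -> np.ndarray:
    """Return the boolean dye mask of ``image`` under the RGB threshold box.

    The classification is pointwise: each pixel is tested independently
    against the box, so the mask has exactly the image's height and width.
    """
    threshold = threshold or DyeThreshold()
    arr = _as_rgb(image).astype(np.int16)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    return (
        (r <= threshold.r_max)
        & (g <= threshold.g_max)
        & (b >= threshold.b_min)
        & (b <= threshold.b_max)
    )


def _round_half_down(v: np.ndarray) -> np.ndarray:
    # nearest integer, exact .5 ties toward the smaller index (determinism)
    return np.ceil(np.asarray(v) - 0.5)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit direction (d_row, d_col) of the least-squares line through points."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def extract_interface_markers(
    mask: np.ndarray,
    margin_anchor: tuple[int, int],
    bin_width: float = 5.0,
) -> MarkerTrace:
    """Place one marker per occupied bin along the dye region's principal axis.

    Dye pixels are projected onto the principal axis of the dye region and
    binned with ``bin_width``; each occupied bin yields the centroid of its
    pixels, rounded to the nearest pixel.  Markers are ordered starting
    from the end nearest ``margin_anchor``.  An all-false mask yields an
    empty trace.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    r0, c0 = margin_anchor
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise ValueError(
            f"margin_anchor {margin_anchor} outside image bounds {mask.shape}"
        )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    pts = np.argwhere(mask).astype(float)  # (n, 2) rows of (row, col)
    anchor = np.asarray(margin_anchor, dtype=float)
    if len(pts) == 0:
        return MarkerTrace(np.empty((0, 2)), tuple(anchor))
    if len(pts) == 1:
        return MarkerTrace(pts.copy(), tuple(anchor), axis=None, span_px=0.0)

    axis = _principal_axis(pts)
    t = (pts - pts.mean(axis=0)) @ axis
    # orient the axis so the margin anchor sits at the low-t end
    t_anchor = (anchor - pts.mean(axis=0)) @ axis
    if abs(t_anchor - t.max()) < abs(t_anchor - t.min()):
        axis = -axis
        t = -t
    t0 = t.min()
    span = float(t.max() - t0)
    if span < 1e-9:
        centroid = _round_half_down(pts.mean(axis=0))
        return MarkerTrace(centroid[None, :], tuple(anchor), axis=axis, span_px=0.0)

    bins = np.floor((t - t0) / bin_width).astype(int)
    markers: list[tuple[float, float]] = []
    seen: set[tuple[float, float]] = set()
    for b in np.unique(bins):  # ascending = margin first
        centroid = _round_half_down(pts[bins == b].mean(axis=0))
        key = (float(centroid[0]), float(centroid[1]))
        if key not in seen:
            seen.add(key)
            markers.append(key)
    return MarkerTrace(np.array(markers), tuple(anchor), axis=axis, span_px=span)


def render_markers(
    image: np.ndarray,
    trace: MarkerTrace,
    color: tuple[int, int, int] = MARKER_COLOR,
) -> np.ndarray:
    """Return a copy of ``image`` with the trace's marker pixels painted.

    Markers are painted as green (0, 255, 0) single pixels by default;
    every other pixel is left untouched.
    """
    out = _as_rgb(image).copy()
    if trace.is_empty:
        return out
    rows = _round_half_down(trace.markers[:, 0]).astype(int)
    cols = _round_half_down(trace.markers[:, 1]).astype(int)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= out.shape[0]
        or cols.max() >= out.shape[1]
    ):
        raise ValueError("trace markers fall outside the image bounds")
    out[rows, cols] = color
    return out
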