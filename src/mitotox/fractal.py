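"""Box-counting fractal dimensions of binarized perturbation maps.

A grayscale LPRS map is thresholded to black/white; three pixel sets are
measured: the black/white border, black∪border and white∪border.  Each
set's box-counting dimension is the slope of log N(ε) against log(1/ε),
where N(ε) counts occupied ε×ε grid cells (grid anchored at the origin).
The border dimension tracks the geometric complexity of the perturbation
pattern's interface; the union dimensions are near 2 for space-filling
patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError


@dataclass(frozen=True)
class BinaryMap:
    """Boolean foreground grid (True = black = high perturbation)."""

    pixels: np.ndarray
    threshold_used: float
    source: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or min(px.shape) < 8:
            raise DegenerateImageError("binary map must be at least 8×8")
        if px.all() or not px.any():
            raise DegenerateImageError("binary map needs both colors for border analysis")


def binarize(image: np.ndarray, method: str = "otsu",
             fixed_threshold: float | None = None, source: str = "") -> BinaryMap:
    """Deterministic thresholding: black = values above the threshold.

    ``otsu`` picks the threshold maximizing between-class variance;
    ``fixed`` uses ``fixed_threshold`` directly.  A constant image has no
    contrast and raises.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise DegenerateImageError("image contains non-finite values")
    if np.ptp(image) == 0:
        raise DegenerateImageError("constant image cannot be binarized")
    if method == "otsu":
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMap(image > thr, thr, source)


def extract_sets(b: BinaryMap) -> dict[str, np.ndarray]:
    """Border, black∪border and white∪border pixel sets.

    A border pixel has at least one 4-neighbor of the opposite color; the
    border is a subset of both unions by construction.
    """
    px = b.pixels
    opposite = np.zeros_like(px)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(px, shift, axis=axis)
        # edge rows/columns have no neighbour beyond the frame
        if axis == 0:
            rolled[0 if shift == 1 else -1, :] = px[0 if shift == 1 else -1, :]
        else:
            rolled[:, 0 if shift == 1 else -1] = px[:, 0 if shift == 1 else -1]
        opposite |= rolled != px
    border = opposite
    return {
        "border": border,
        "black_union": px | border,
        "white_union": (~px) | border,
    }


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 up to min(H, W)/4."""
    limit = min(shape) // 4
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def box_count(pixel_set: np.ndarray, size: int) -> int:
    """Occupied size×size cells of the origin-anchored grid (the trailing
    partial row/column of boxes is included)."""
    h, w = pixel_set.shape
    ph, pw = -h % size, -w % size
    padded = np.pad(pixel_set, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // size, size, padded.shape[1] // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(pixel_set: np.ndarray, box_sizes) -> tuple[float, list[tuple[int, int]], float]:
    """Least-squares slope of log N(ε) versus log(1/ε).

    Returns (dimension, [(ε, N(ε))...], r² of the log–log fit).
    """
    pixel_set = np.asarray(pixel_set, dtype=bool)
    if not pixel_set.any():
        raise ValueError("empty pixel set has no box-counting dimension")
    box_sizes = sorted(set(int(s) for s in box_sizes))
    if len(box_sizes) < 4:
        raise ValueError("need at least 4 box sizes")
    if box_sizes[0] < 1 or box_sizes[-1] > min(pixel_set.shape):
        raise ValueError("box sizes must lie between 1 and the image extent")
    points = [(s, box_count(pixel_set, s)) for s in box_sizes]
    x = np.log(1.0 / np.array([s for s, _ in points], dtype=float))
    y = np.log(np.array([c for _, c in points], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), points, r2


@dataclass(frozen=True)
class FractalResult:
    """The three box-counting dimensions of one binarized map."""

    d_bw: float          # border set
    d_bbw: float         # black ∪ border
    d_wbw: float         # white ∪ border
    fit_points: dict
    fit_r_squared: dict
    threshold_used: float

    def as_dict(self) -> dict:
        return {
            "D_BW": self.d_bw,
            "D_B+BW": self.d_bbw,
            "D_W+BW": self.d_wbw,
            "fit_r_squared": self.fit_r_squared,
            "threshold": self.threshold_used,
        }

    def to_json(self) -> str:
        payload = self.as_dict()
        payload["fit_points"] = {k: [[int(s), int(c)] for s, c in v]
                                 for k, v in self.fit_points.items()}
        return json.dumps(payload, indent=2)


def fractal_report(image: np.ndarray, method: str = "otsu",
                   fixed_threshold: float | None = None,
                   box_sizes=None) -> FractalResult:
    """Binarize a grayscale map and measure its three dimensions."""
    binary = binarize(image, method, fixed_threshold)
    sets = extract_sets(binary)
    sizes = box_sizes if box_sizes is not None else default_box_sizes(binary.pixels.shape)
    dims, pts, r2s = {}, {}, {}
    for name, px in sets.items():
        dims[name], pts[name], r2s[name] = box_count_dimension(px, sizes)
    return FractalResult(
        d_bw=dims["border"],
        d_bbw=dims["black_union"],
        d_wbw=dims["white_union"],
        fit_points=pts,
        fit_r_squared=r2s,
        threshold_used=binary.threshold_used,
    )
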