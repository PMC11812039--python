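"""Box-counting fractal dimension of rasterized trees.

The fractal dimension D is the exponent in N = (1/r)**D, the number of
boxes of width r needed to cover a shape.  Here it is measured on a binary
image by overlaying dyadic grids of 2^1, 2^2, ... boxes across the image
width, counting occupied boxes at each scale, and regressing log2 N on
log2 (boxes across the width).  A filled plane gives D = 2, a one-pixel
line D = 1, a single point D = 0; tree silhouettes land in between, higher
for higher radius scaling exponents because they carry more branches.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .simulate import TreeModel

__all__ = [
    "BinaryImage",
    "BoxCountResult",
    "rasterize_tree",
    "box_count_dimension",
]


@dataclass(frozen=True)
class BinaryImage:
    """Square boolean occupancy grid with power-of-two side length."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.ndim != 2 or occ.shape[0] != occ.shape[1]:
            raise ValueError("occupancy must be a square 2-D grid")
        size = occ.shape[0]
        if size < 2 or size & (size - 1):
            raise ValueError("image side must be a power of two >= 2")
        object.__setattr__(self, "occupancy", occ)

    @property
    def size(self) -> int:
        return int(self.occupancy.shape[0])

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


@dataclass(frozen=True)
class BoxCountResult:
    """Occupied-box counts across dyadic grids and the regression slope."""

    grid_sizes: tuple[int, ...]       # boxes across the image width
    occupied_counts: tuple[int, ...]
    dimension: float
    regression_intercept: float
    r_squared: float


def rasterize_tree(tree: TreeModel, size: int = 256,
                   margin: float = 0.05) -> BinaryImage:
    """Draw a tree into a binary image, each limb a round-capped stroke.

    Stroke width equals the branch diameter after the whole tree is scaled
    uniformly so its ink bounding box fits within ``(1 - 2*margin)*size``
    pixels.  Rendering is binary (no anti-aliasing) and deterministic.
    """
    if size < 2 or size & (size - 1):
        raise ValueError("size must be a power of two >= 2")
    if not 0.0 <= margin < 0.5:
        raise ValueError("margin must lie in [0, 0.5)")
    if not tree.branches:
        raise ValueError("tree has no branches")

    # ink bounding box: endpoints padded by each stroke's radius
    xs, ys = [], []
    for b in tree.branches:
        for (px, py) in (b.start_point, b.end_point):
            xs.extend([px - b.radius, px + b.radius])
            ys.extend([py - b.radius, py + b.radius])
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    span = max(x1 - x0, y1 - y0)
    if span <= 0:
        raise ValueError("tree has a degenerate bounding box")
    scale = (1.0 - 2.0 * margin) * size / span
    # center the tree; image rows grow downward while the tree grows upward
    ox = (size - scale * (x1 - x0)) / 2.0 - scale * x0
    oy = (size - scale * (y1 - y0)) / 2.0 - scale * y0

    img = Image.new("1", (size, size), 0)
    draw = ImageDraw.Draw(img)

    def to_px(p: tuple[float, float]) -> tuple[float, float]:
        return (scale * p[0] + ox, size - (scale * p[1] + oy))

    for b in tree.branches:
        ax, ay = to_px(b.start_point)
        bx, by = to_px(b.end_point)
        w = max(1.0, scale * b.diameter)
        draw.line([(ax, ay), (bx, by)], fill=1, width=int(round(w)))
        r = w / 2.0
        for (cx, cy) in ((ax, ay), (bx, by)):  # round caps
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=1)
    return BinaryImage(np.array(img, dtype=bool))


def _occupied_boxes(occ: np.ndarray, boxes_across: int,
                    offset: tuple[int, int] = (0, 0)) -> int:
    size = occ.shape[0]
    s = size // boxes_across
    if offset != (0, 0):
        shifted = np.zeros_like(occ)
        dy, dx = offset
        shifted[dy:, dx:] = occ[:size - dy, :size - dx]
        if dy:
            shifted[:dy, dx:] = occ[size - dy:, :size - dx]
        occ = shifted
    blocks = occ.reshape(boxes_across, s, boxes_across, s)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count_dimension(image: BinaryImage,
                        grid_exponents: Sequence[int] | None = None,
                        offset_average: bool = False) -> BoxCountResult:
    """Regression estimate of the box-counting dimension.

    ``grid_exponents`` lists the dyadic scales to use: exponent e means a
    grid of 2**e boxes across the width.  The default uses every scale from
    2^1 up to one box per pixel; the single-box scale 2^0 is excluded since
    its count is identically 1.  Grids are aligned to the image origin;
    ``offset_average`` instead averages counts over four half-box grid
    offsets (a smoothing variant, off by default).
    """
    occ = image.occupancy
    if not occ.any():
        raise ValueError("image has no occupied pixels")
    max_exp = int(math.log2(image.size))
    if grid_exponents is None:
        grid_exponents = range(1, max_exp + 1)
    exps = sorted(set(int(e) for e in grid_exponents))
    if len(exps) < 2:
        raise ValueError("need at least two grid scales for a regression")
    if exps[0] < 1 or exps[-1] > max_exp:
        raise ValueError(f"grid exponents must lie in [1, {max_exp}]")

    grid_sizes = [2 ** e for e in exps]
    counts: list[float] = []
    for g in grid_sizes:
        if offset_average:
            half = (image.size // g) // 2
            offs = [(0, 0), (0, half), (half, 0), (half, half)]
            counts.append(float(np.mean([_occupied_boxes(occ, g, o) for o in offs])))
        else:
            counts.append(float(_occupied_boxes(occ, g)))

    x = np.log2(np.asarray(grid_sizes, dtype=float))
    y = np.log2(np.asarray(counts))
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(residuals ** 2)) / ss_tot
    return BoxCountResult(grid_sizes=tuple(grid_sizes),
                          occupied_counts=tuple(int(round(c)) for c in counts),
                          dimension=float(slope),
                          regression_intercept=float(intercept),
                          r_squared=r2)
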