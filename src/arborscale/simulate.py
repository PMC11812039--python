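"""Seeded random self-similar trees and power-law diameter samples.

The generator grows a binary tree from a single trunk.  At every
ramification a proportion u between the two children is drawn uniformly,
child radii are solved so that r_a^alpha + r_b^alpha = r_c^alpha holds
exactly, and child lengths are solved the same way with the length
exponent beta and the same u (slimmer children are also shorter).  A limb
whose radius falls below ``stop_ratio`` times the trunk radius is kept but
not subdivided further.  Because each ramification doubles the downstream
branch count while higher alpha shrinks radii more slowly, raising alpha
packs exponentially more branches into the same radius range.

``sample_diameters`` draws directly from the power-law diameter
distribution the estimator assumes, P(d >= x) = (xm/x)**alpha for x >= xm,
which is the distribution implied for a randomly selected branch by the
branch-count relation n = (r0/r)**alpha.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .samples import DiameterSample
from .scaling import complete_triplet

__all__ = [
    "BranchSegment",
    "TreeModel",
    "ResourceLimitError",
    "generate_tree",
    "sample_diameters",
    "tree_to_diameters",
    "tree_to_svg",
]


class ResourceLimitError(RuntimeError):
    """Raised when tree generation would exceed the branch budget."""


@dataclass(frozen=True)
class BranchSegment:
    """One limb: a straight stroke with a radius, in tree coordinates."""

    id: int
    parent_id: int | None
    radius: float
    length: float
    generation: int
    start_point: tuple[float, float]
    angle: float  # radians, measured from +x; the trunk points along +y

    @property
    def end_point(self) -> tuple[float, float]:
        return (self.start_point[0] + self.length * math.cos(self.angle),
                self.start_point[1] + self.length * math.sin(self.angle))

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class TreeModel:
    """A generated tree plus the parameters that produced it."""

    branches: tuple[BranchSegment, ...]
    trunk_radius: float
    alpha: float
    beta: float
    stop_ratio: float
    asymmetry_low: float
    asymmetry_high: float
    seed: int
    trunk_length: float
    branch_angle: float
    angle_jitter: float

    def __len__(self) -> int:
        return len(self.branches)

    @property
    def root(self) -> BranchSegment:
        return self.branches[0]

    def terminal_branches(self) -> list[BranchSegment]:
        parents = {b.parent_id for b in self.branches if b.parent_id is not None}
        return [b for b in self.branches if b.id not in parents]


def generate_tree(alpha: float,
                  beta: float = 2.0,
                  stop_ratio: float = 0.1,
                  asymmetry_low: float = 0.6,
                  asymmetry_high: float = 1.0,
                  seed: int = 0,
                  trunk_radius: float = 1.0,
                  trunk_length: float = 6.0,
                  branch_angle: float = 0.35,
                  angle_jitter: float = 0.15,
                  branch_budget: int = 1_000_000) -> TreeModel:
    """Grow a random self-similar binary tree.

    Parameters
    ----------
    alpha
        Radius scaling exponent preserved at every ramification.
    beta
        Length scaling exponent (same relation applied to limb lengths).
    stop_ratio
        A limb thinner than ``stop_ratio * trunk_radius`` is not subdivided.
    asymmetry_low, asymmetry_high
        Range of the smaller:larger child ratio u drawn at each
        ramification; (1, 1) gives a perfectly symmetric tree.
    seed
        Seeds the single random stream; identical parameters and seed give
        a bit-identical branch list.  Draws are consumed depth-first,
        child-a-first: at each ramification u, then the two angle jitters,
        then the whole subtree of the slimmer child a.
    trunk_radius, trunk_length, branch_angle, angle_jitter
        Geometry: trunk dimensions, mean half-opening angle between the
        parent direction and each child (radians), and the uniform jitter
        half-width added to it.
    branch_budget
        Hard cap on total segments; exceeding it raises
        :class:`ResourceLimitError` rather than recursing away.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not 0.0 < stop_ratio < 1.0:
        raise ValueError("stop_ratio must lie in (0, 1)")
    if not 0.0 < asymmetry_low <= asymmetry_high <= 1.0:
        raise ValueError("need 0 < asymmetry_low <= asymmetry_high <= 1")
    if trunk_radius <= 0 or trunk_length <= 0:
        raise ValueError("trunk dimensions must be positive")

    rng = np.random.Generator(np.random.PCG64(seed))
    stop_radius = stop_ratio * trunk_radius
    branches: list[BranchSegment] = []

    trunk = BranchSegment(id=0, parent_id=None, radius=trunk_radius,
                          length=trunk_length, generation=0,
                          start_point=(0.0, 0.0), angle=math.pi / 2.0)
    branches.append(trunk)

    def subdivide(parent: BranchSegment) -> None:
        if parent.radius < stop_radius:
            return
        if len(branches) + 2 > branch_budget:
            raise ResourceLimitError(
                f"branch budget of {branch_budget} segments exceeded; "
                "raise the budget or the stop_ratio")
        u = rng.uniform(asymmetry_low, asymmetry_high)
        jitter_a = rng.uniform(-angle_jitter, angle_jitter)
        jitter_b = rng.uniform(-angle_jitter, angle_jitter)
        r_a, r_b = complete_triplet(parent.radius, u, alpha)
        l_a, l_b = complete_triplet(parent.length, u, beta)
        base = parent.end_point
        child_a = BranchSegment(id=len(branches), parent_id=parent.id,
                                radius=r_a, length=l_a,
                                generation=parent.generation + 1,
                                start_point=base,
                                angle=parent.angle + branch_angle + jitter_a)
        branches.append(child_a)
        subdivide(child_a)
        child_b = BranchSegment(id=len(branches), parent_id=parent.id,
                                radius=r_b, length=l_b,
                                generation=parent.generation + 1,
                                start_point=base,
                                angle=parent.angle - branch_angle - jitter_b)
        branches.append(child_b)
        subdivide(child_b)

    subdivide(trunk)
    return TreeModel(branches=tuple(branches), trunk_radius=trunk_radius,
                     alpha=alpha, beta=beta, stop_ratio=stop_ratio,
                     asymmetry_low=asymmetry_low, asymmetry_high=asymmetry_high,
                     seed=seed, trunk_length=trunk_length,
                     branch_angle=branch_angle, angle_jitter=angle_jitter)


def sample_diameters(alpha: float, xm: float, n: int, seed: int = 0,
                     source_label: str = "pareto") -> DiameterSample:
    """Draw n diameters from the tail law P(d >= x) = (xm/x)**alpha.

    Inverse-transform sampling: d = xm * U**(-1/alpha) with U uniform on
    (0, 1], so U = 1 maps to the cutoff xm itself.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if xm <= 0:
        raise ValueError("xm must be positive")
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.Generator(np.random.PCG64(seed))
    u = 1.0 - rng.random(n)  # uniform on (0, 1]
    d = xm * u ** (-1.0 / alpha)
    return DiameterSample(d, unit="user", source_label=source_label,
                          replicate_tag=f"seed{seed}")


def tree_to_diameters(tree: TreeModel, noise_cv: float = 0.0,
                      seed: int = 0) -> DiameterSample:
    """List every branch diameter of a tree, emulating hand annotation.

    Each diameter (twice the radius) is multiplied by an independent
    lognormal factor with median 1 and coefficient of variation
    ``noise_cv``, modelling measurement error; ``noise_cv=0`` returns the
    exact diameters.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    d = np.array([b.diameter for b in tree.branches], dtype=float)
    if noise_cv > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        sigma = math.sqrt(math.log1p(noise_cv ** 2))
        d = d * rng.lognormal(mean=0.0, sigma=sigma, size=d.size)
    return DiameterSample(d, unit="user",
                          source_label=f"tree(alpha={tree.alpha},seed={tree.seed})",
                          replicate_tag=f"noise{noise_cv}")


def tree_to_svg(tree: TreeModel, canvas: float = 512.0,
                margin_frac: float = 0.05) -> str:
    """Render a tree as an SVG string, one round-capped line per limb."""
    xs, ys = [], []
    for b in tree.branches:
        for (px, py) in (b.start_point, b.end_point):
            xs.extend([px - b.radius, px + b.radius])
            ys.extend([py - b.radius, py + b.radius])
    x0, x1, y0, y1 = min(xs), max(xs), min(ys), max(ys)
    span = max(x1 - x0, y1 - y0)
    if span <= 0:
        raise ValueError("tree has a degenerate bounding box")
    scale = (1.0 - 2.0 * margin_frac) * canvas / span
    ox = (canvas - scale * (x1 - x0)) / 2.0 - scale * x0
    oy = (canvas - scale * (y1 - y0)) / 2.0 - scale * y0
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{canvas:g}" height="{canvas:g}" '
        f'viewBox="0 0 {canvas:g} {canvas:g}">'
    ]
    for b in tree.branches:
        (ax, ay), (bx, by) = b.start_point, b.end_point
        lines.append(
            f'<line x1="{scale * ax + ox:.3f}" y1="{canvas - (scale * ay + oy):.3f}" '
            f'x2="{scale * bx + ox:.3f}" y2="{canvas - (scale * by + oy):.3f}" '
            f'stroke="black" stroke-width="{scale * b.diameter:.3f}" '
            'stroke-linecap="round"/>')
    lines.append("</svg>")
    return "\n".join(lines)
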