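"""Generalized da Vinci branching mathematics.

A self-similar tree preserves the quantity r^alpha across every
ramification: where a proximal limb of radius r_c divides into distal limbs
of radii r_a and r_b,

    r_a**alpha + r_b**alpha == r_c**alpha.

alpha = 2 is da Vinci's rule (cross-sectional area preserved); alpha = 3 is
Murray's law (flow proportional to r**3).  The same exponent governs the
approximate number of branches of a given radius, n = (r0/r)**alpha, where
r0 is the trunk radius.  Both relations are homogeneous of degree alpha, so
any constant coefficient — units, or the factor 2 between radius and
diameter — cancels; every function here accepts radii and diameters
interchangeably.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .simulate import TreeModel

__all__ = [
    "BranchTriplet",
    "FlowModel",
    "symmetric_child_radius",
    "complete_triplet",
    "branch_count",
    "check_flow_conservation",
]


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class BranchTriplet:
    """One ramification: a parent limb and its two children.

    Valid triplets satisfy the conservation relation
    ``child_a_radius**alpha + child_b_radius**alpha == parent_radius**alpha``
    to within a relative tolerance of 1e-9, and both children are strictly
    thinner than the parent.
    """

    parent_radius: float
    child_a_radius: float
    child_b_radius: float
    alpha: float

    def __post_init__(self) -> None:
        _require_positive(parent_radius=self.parent_radius,
                          child_a_radius=self.child_a_radius,
                          child_b_radius=self.child_b_radius,
                          alpha=self.alpha)
        if not (self.child_a_radius < self.parent_radius
                and self.child_b_radius < self.parent_radius):
            raise ValueError("children must be strictly thinner than the parent")
        lhs = self.child_a_radius ** self.alpha + self.child_b_radius ** self.alpha
        rhs = self.parent_radius ** self.alpha
        if abs(lhs - rhs) > 1e-9 * rhs:
            raise ValueError(
                f"radii violate conservation: {lhs!r} != {rhs!r} at alpha={self.alpha}")


@dataclass(frozen=True)
class FlowModel:
    """Phenomenological flow law f(r) = coefficient * r**alpha.

    The coefficient cancels from every ratio and is retained only for
    documentation; only the exponent matters for proportions and counts.
    """

    alpha: float
    coefficient: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha, coefficient=self.coefficient)

    def flow(self, radius: float) -> float:
        _require_positive(radius=radius)
        return self.coefficient * radius ** self.alpha


def symmetric_child_radius(parent_radius: float, alpha: float) -> float:
    """Radius of each of two equal children of a parent limb.

    Two children of radius ``parent_radius * 2**(-1/alpha)`` conserve
    r^alpha exactly.  At alpha=1 this halves the parent, at alpha=2 it is
    the Pythagorean factor 1/sqrt(2), and at alpha=3 it is the
    cube-doubling ratio 2**(-1/3).
    """
    _require_positive(parent_radius=parent_radius, alpha=alpha)
    return parent_radius * 2.0 ** (-1.0 / alpha)


def complete_triplet(parent_radius: float, ratio_ab: float,
                     alpha: float) -> tuple[float, float]:
    """Solve a ramification for both child radii given their ratio.

    The conservation relation alone leaves a one-parameter family of child
    pairs; fixing the proportion ``ratio_ab = child_a / child_b`` pins the
    pair down.  Closed form:

        child_b = parent_radius * (1 + ratio_ab**alpha) ** (-1/alpha)
        child_a = ratio_ab * child_b

    Returns ``(child_a_radius, child_b_radius)``.
    """
    _require_positive(parent_radius=parent_radius, ratio_ab=ratio_ab, alpha=alpha)
    child_b = parent_radius * (1.0 + ratio_ab ** alpha) ** (-1.0 / alpha)
    return ratio_ab * child_b, child_b


def branch_count(trunk_radius: float, radius: float, alpha: float) -> float:
    """Approximate number of branches of radius ``radius`` in a tree.

    Counting transects that cut every root-to-leaf path exactly once,
    n branches of radius r must jointly carry the trunk's flow, giving
    ``n = (trunk_radius / radius) ** alpha``.  Exact for ideal symmetric
    trees, approximate for random asymmetric ones.
    """
    _require_positive(trunk_radius=trunk_radius, radius=radius, alpha=alpha)
    if radius > trunk_radius:
        raise ValueError(
            f"radius {radius!r} exceeds trunk radius {trunk_radius!r}")
    return (trunk_radius / radius) ** alpha


def check_flow_conservation(tree: "TreeModel", alpha: float) -> float:
    """Worst relative flow-conservation violation over all tree transects.

    Each tree depth level, completed to a full transect by carrying through
    terminal limbs that stopped at a shallower depth, must carry the same
    total r^alpha as the trunk.  Returns

        max over depths d of |sum_i r_i^alpha - r0^alpha| / r0^alpha,

    which is 0 (up to floating point) for a tree generated with the same
    alpha and strictly positive if the exponents disagree at any
    asymmetric ramification.
    """
    _require_positive(alpha=alpha)
    branches = list(tree.branches)
    if not branches:
        raise ValueError("tree has no branches")

    children_of: dict[int, list[int]] = {}
    by_id = {}
    root = None
    for b in branches:
        by_id[b.id] = b
        if b.parent_id is None:
            root = b
        else:
            children_of.setdefault(b.parent_id, []).append(b.id)
    if root is None:
        raise ValueError("tree has no root")

    trunk_flow = root.radius ** alpha
    max_depth = max(b.generation for b in branches)
    worst = 0.0
    for depth in range(max_depth + 1):
        # transect at this depth: branches born here, plus terminals that
        # stopped shallower and are carried through unbranched
        total = 0.0
        for b in branches:
            if b.generation == depth or (
                    b.generation < depth and b.id not in children_of):
                total += b.radius ** alpha
        worst = max(worst, abs(total - trunk_flow) / trunk_flow)
    return worst
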