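"""Flat bags of branch-diameter measurements.

A diameter sample deliberately records no topology: counting how many
branches exist at each magnitude of diameter is a far more robust route to
the radius scaling exponent than solving the branching relation at
individual ramifications, so the measurement protocol keeps only the bag of
diameters together with provenance (unit, source, replicate).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DiameterSample:
    """A list of branch diameters with measurement provenance.

    Parameters
    ----------
    diameters
        Positive branch diameters. Order carries no meaning and duplicates
        are allowed.
    unit
        Physical unit of the diameters (e.g. ``"cm"``), or ``"user"`` when
        lengths are in annotation user units. Scaling exponents are
        scale-free, so the unit never affects estimation.
    source_label
        Identifier of the artwork, tree, or simulation the sample came from.
    replicate_tag
        Observer or replicate identifier; replicates are fitted separately.
    """

    diameters: np.ndarray
    unit: str = "user"
    source_label: str = ""
    replicate_tag: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.diameters, dtype=float)
        if arr.ndim != 1:
            raise ValueError("diameters must be a flat, one-dimensional list")
        if arr.size == 0:
            raise ValueError("diameter sample is empty")
        if not np.all(np.isfinite(arr)):
            raise ValueError("diameters must be finite")
        if np.any(arr <= 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValueError(f"diameters must be positive (index {bad} is {arr[bad]!r})")
        arr.flags.writeable = False
        object.__setattr__(self, "diameters", arr)

    def __len__(self) -> int:
        return int(self.diameters.size)

    def scaled(self, factor: float) -> "DiameterSample":
        """Return a copy with every diameter multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return DiameterSample(self.diameters * factor, self.unit,
                              self.source_label, self.replicate_tag)
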