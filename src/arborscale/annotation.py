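"""Read hand-annotated SVG files and plain CSV lists into diameter samples.

The annotation protocol overlays one straight line segment, drawn
perpendicular to a branch, per branch diameter.  This module extracts every
straight-line mark from such a file — native ``line`` elements and
two-point ``path`` elements in absolute or relative coordinates — applies
the full affine transform stack, and reports Euclidean lengths as
diameters.  Curves and multi-segment paths are not diameter marks and are
skipped with a logged count.

Exponent estimation is scale-free, so lengths may stay in SVG user units;
when the document declares a physical width and a viewBox a units-per-cm
factor is derived, and an explicit ``scale`` always wins.
"""
from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .samples import DiameterSample

__all__ = [
    "AnnotationDocument",
    "AnnotationError",
    "EmptySampleError",
    "read_svg_annotations",
    "read_csv_diameters",
    "write_csv_diameters",
]

log = logging.getLogger(__name__)

_INKSCAPE_LABEL = "{http://www.inkscape.org/namespaces/inkscape}label"

# user units per physical unit, relative to the CSS px
_UNIT_PER_PX = {"px": 1.0, "pt": 96.0 / 72.0, "pc": 16.0, "in": 96.0,
                "cm": 96.0 / 2.54, "mm": 96.0 / 25.4, "": 1.0}


class AnnotationError(ValueError):
    """The file or an element in it cannot be interpreted."""


class EmptySampleError(AnnotationError):
    """No straight-line annotation marks were found."""


@dataclass(frozen=True)
class AnnotationDocument:
    """Flat list of annotation segments in user units, plus unit metadata."""

    segments: list[tuple[float, float, float, float]]
    user_units_per_physical_unit: float | None = None
    physical_unit: str | None = None


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


_TRANSFORM_RE = re.compile(r"(\w+)\s*\(([^)]*)\)")


def _parse_transform(text: str) -> np.ndarray:
    """Compose an SVG transform attribute into a 3x3 affine matrix."""
    m = np.eye(3)
    for name, argtext in _TRANSFORM_RE.findall(text or ""):
        args = [float(v) for v in re.split(r"[\s,]+", argtext.strip()) if v]
        t = np.eye(3)
        if name == "translate":
            t[0, 2] = args[0]
            t[1, 2] = args[1] if len(args) > 1 else 0.0
        elif name == "scale":
            t[0, 0] = args[0]
            t[1, 1] = args[1] if len(args) > 1 else args[0]
        elif name == "rotate":
            a = math.radians(args[0])
            rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                            [math.sin(a), math.cos(a), 0.0],
                            [0.0, 0.0, 1.0]])
            if len(args) == 3:
                cx, cy = args[1], args[2]
                pre = np.eye(3); pre[0, 2], pre[1, 2] = cx, cy
                post = np.eye(3); post[0, 2], post[1, 2] = -cx, -cy
                t = pre @ rot @ post
            else:
                t = rot
        elif name == "matrix":
            a, b, c, d, e, f = args
            t = np.array([[a, c, e], [b, d, f], [0.0, 0.0, 1.0]])
        elif name == "skewX":
            t[0, 1] = math.tan(math.radians(args[0]))
        elif name == "skewY":
            t[1, 0] = math.tan(math.radians(args[0]))
        else:
            raise AnnotationError(f"unsupported transform {name!r}")
        m = m @ t
    return m


_PATH_TOKEN_RE = re.compile(r"([MmLlHhVvZzCcSsQqTtAa])|(-?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def _path_points(d: str) -> list[tuple[float, float]] | None:
    """Resolve a path's vertices; None if it contains curves or closure.

    Supports absolute/relative moveto, lineto, and horizontal/vertical
    lineto, including implicit lineto after moveto.
    """
    tokens = _PATH_TOKEN_RE.findall(d or "")
    points: list[tuple[float, float]] = []
    cmd = None
    x = y = 0.0
    nums: list[float] = []
    i = 0
    flat = [(c if c else None, float(n) if n else None) for c, n in tokens]
    while i < len(flat):
        c, n = flat[i]
        if c is not None:
            if c in "CcSsQqTtAaZz":
                return None  # curve or closed subpath: not a diameter mark
            cmd = c
            i += 1
            continue
        # collect the numbers this command needs
        need = 1 if cmd in "HhVv" else 2
        nums = []
        while len(nums) < need and i < len(flat) and flat[i][0] is None:
            nums.append(flat[i][1])
            i += 1
        if len(nums) < need:
            return None
        if cmd in "Mm":
            if cmd == "m" and points:
                x, y = x + nums[0], y + nums[1]
            elif cmd == "m":
                x, y = nums[0], nums[1]  # relative moveto at start is absolute
            else:
                x, y = nums[0], nums[1]
            # subsequent pairs are implicit linetos
            cmd = "l" if cmd == "m" else "L"
        elif cmd == "L":
            x, y = nums[0], nums[1]
        elif cmd == "l":
            x, y = x + nums[0], y + nums[1]
        elif cmd == "H":
            x = nums[0]
        elif cmd == "h":
            x = x + nums[0]
        elif cmd == "V":
            y = nums[0]
        elif cmd == "v":
            y = y + nums[0]
        else:
            return None
        points.append((x, y))
    return points


def _parse_length(text: str | None) -> tuple[float, str] | None:
    if not text:
        return None
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-z%]*)\s*", text)
    if not m or m.group(2) == "%":
        return None
    return float(m.group(1)), m.group(2)


def _physical_scale(root) -> tuple[float, str] | None:
    """Units-per-cm factor from the document width/viewBox, if declared."""
    width = _parse_length(root.get("width"))
    viewbox = root.get("viewBox")
    if width is None or viewbox is None:
        return None
    value, unit = width
    if unit in ("", "px"):
        return None  # no physical claim
    parts = [float(v) for v in re.split(r"[\s,]+", viewbox.strip()) if v]
    if len(parts) != 4 or parts[2] <= 0:
        return None
    width_cm = value * _UNIT_PER_PX[unit] / _UNIT_PER_PX["cm"]
    return parts[2] / width_cm, "cm"  # user units per cm


def _in_layer(element, layer_filter: str) -> bool:
    node = element
    while node is not None:
        if _local(node.tag) == "g":
            if node.get("id") == layer_filter \
                    or node.get(_INKSCAPE_LABEL) == layer_filter:
                return True
        node = node.getparent()
    return False


def read_svg_document(path: str | Path,
                      layer_filter: str | None = None) -> AnnotationDocument:
    """Extract all straight annotation segments from an SVG file."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise AnnotationError(f"cannot parse SVG file {path}: {exc}") from exc
    root = tree.getroot()

    segments: list[tuple[float, float, float, float]] = []
    n_curves = 0
    n_zero = 0
    for element in root.iter():
        tag = _local(element.tag)
        if tag not in ("line", "path"):
            continue
        if layer_filter is not None and not _in_layer(element, layer_filter):
            continue
        if tag == "line":
            try:
                pts = [(float(element.get("x1", "0")), float(element.get("y1", "0"))),
                       (float(element.get("x2", "0")), float(element.get("y2", "0")))]
            except (TypeError, ValueError) as exc:
                raise AnnotationError(
                    f"malformed line element id={element.get('id')!r}") from exc
        else:
            pts = _path_points(element.get("d", ""))
            if pts is None:
                n_curves += 1
                continue
            if len(pts) != 2:
                n_curves += 1  # polyline, not a single diameter mark
                continue
        # compose transforms from the root down to this element
        matrix = np.eye(3)
        chain = [element]
        node = element.getparent()
        while node is not None:
            chain.append(node)
            node = node.getparent()
        for node in reversed(chain):
            matrix = matrix @ _parse_transform(node.get("transform", ""))
        (x1, y1), (x2, y2) = pts
        p1 = matrix @ np.array([x1, y1, 1.0])
        p2 = matrix @ np.array([x2, y2, 1.0])
        if not np.all(np.isfinite(p1)) or not np.all(np.isfinite(p2)):
            raise AnnotationError(
                f"non-finite coordinates in element id={element.get('id')!r}")
        if math.hypot(p2[0] - p1[0], p2[1] - p1[1]) == 0.0:
            n_zero += 1
            log.warning("excluding zero-length segment id=%r", element.get("id"))
            continue
        segments.append((float(p1[0]), float(p1[1]), float(p2[0]), float(p2[1])))

    if n_curves:
        log.info("ignored %d curved or multi-segment paths in %s", n_curves, path)
    if not segments:
        raise EmptySampleError(f"no straight-line annotations found in {path}")

    phys = _physical_scale(root)
    if phys is not None:
        per_unit, unit = phys
        return AnnotationDocument(segments, per_unit, unit)
    return AnnotationDocument(segments)


def read_svg_annotations(path: str | Path, layer_filter: str | None = None,
                         scale: float | None = None,
                         source_label: str | None = None,
                         replicate_tag: str = "") -> DiameterSample:
    """Read an annotated SVG into a diameter sample.

    ``scale`` multiplies user-unit lengths into physical units; when omitted
    and the document declares a physical size, a user-units-to-cm factor is
    derived, otherwise lengths stay in user units (harmless for exponent
    estimation, which is scale-free).
    """
    doc = read_svg_document(path, layer_filter=layer_filter)
    lengths = np.array([math.hypot(x2 - x1, y2 - y1)
                        for x1, y1, x2, y2 in doc.segments])
    unit = "user"
    if scale is not None:
        lengths = lengths * scale
        unit = "scaled"
    elif doc.user_units_per_physical_unit is not None:
        lengths = lengths / doc.user_units_per_physical_unit
        unit = doc.physical_unit or "user"
    return DiameterSample(lengths, unit=unit,
                          source_label=source_label or str(path),
                          replicate_tag=replicate_tag)


def read_csv_diameters(path: str | Path, column: str = "diameter",
                       unit: str = "user",
                       source_label: str | None = None,
                       replicate_tag: str = "") -> DiameterSample:
    """Read a one-diameter-per-row CSV (header row required)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if column not in frame.columns:
        raise AnnotationError(
            f"column {column!r} not found in {path}; have {list(frame.columns)}")
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = frame.index[values.isna()]
    if len(bad):
        raise AnnotationError(
            f"non-numeric diameter in {path} at data row(s) {list(bad[:5])}")
    nonpos = frame.index[values <= 0]
    if len(nonpos):
        raise AnnotationError(
            f"non-positive diameter in {path} at data row(s) {list(nonpos[:5])}")
    return DiameterSample(values.to_numpy(dtype=float), unit=unit,
                          source_label=source_label or str(path),
                          replicate_tag=replicate_tag)


def write_csv_diameters(sample: DiameterSample, path: str | Path,
                        column: str = "diameter") -> None:
    """Write a sample as one diameter per row; round-trips at full precision."""
    # shortest round-trip repr per value, so read-after-write is bit exact
    lines = [column] + [repr(float(v)) for v in sample.diameters]
    Path(path).write_text("\n".join(lines) + "\n")
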