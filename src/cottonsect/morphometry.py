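"""Planar geometry and derived fiber metrics.

Every physical number produced by the package flows through this module:
polygon area/perimeter in calibrated micrometers, shape descriptors
(circularity, axis-aligned extents) and the cotton-specific derived
quantities — outer true (wall) area, degree of cell-wall thickening θ,
linear density (fineness, in millitex), maturity ratio and standard
fineness.

Definitions
-----------
For a fiber cross-section with outer (whole-fiber) area ``A_outer``,
outer perimeter ``P_outer`` and lumen area ``A_lumen``:

* ``A_true  = A_outer - A_lumen``            (wall material area, μm²)
* ``θ       = 4π · A_true / P_outer²``       (dimensionless, 1 for a solid disc)
* ``F       = ρ · A_true``                   (fineness, millitex; ρ = 1.52 g/cm³)
* ``M       = θ / 0.577``                    (maturity ratio)
* ``SF      = 0.577 · F / θ``                (standard fineness, millitex)

Circularity of a single closed shape is ``4π·A/P²`` — note θ mixes the
wall area with the *outer* perimeter and is therefore not the
circularity of any one contour.

Coordinates follow the image convention: x rightward, y downward,
0-based pixels. Contours are normalized counter-clockwise (positive
shoelace signed area in (x, y)) on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "COTTON_DENSITY_G_CM3",
    "STANDARD_MATURITY_THETA",
    "MorphometryError",
    "DegenerateContourError",
    "CalibrationScale",
    "Contour",
    "ShapeMeasures",
    "FiberMetrics",
    "polygon_area",
    "polygon_perimeter",
    "circularity",
    "bounding_dims",
    "measure_shape",
    "theta_of",
    "fineness_of",
    "maturity_ratio_of",
    "standard_fineness_of",
    "derive_fiber_metrics",
]

#: Density of cellulose in the cotton fiber wall, g/cm³. Multiplying the
#: wall cross-sectional area in μm² by this constant yields linear
#: density in millitex (1 μm²·g/cm³ = 10⁻⁸ g/cm = 1 mtex).
COTTON_DENSITY_G_CM3 = 1.52

#: θ of a reference fiber of "standard" maturity; the maturity ratio
#: normalizes θ against this value.
STANDARD_MATURITY_THETA = 0.577


class MorphometryError(ValueError):
    """Invalid geometric input."""


class DegenerateContourError(MorphometryError):
    """Contour with (near-)zero area, too few points, or self-intersection."""


@dataclass(frozen=True)
class CalibrationScale:
    """Pixel → micrometer conversion derived from a reference distance.

    Parameters
    ----------
    reference_length_um
        Physical length of the in-image scale reference, μm.
    reference_length_px
        The same reference measured in pixels.
    """

    reference_length_um: float
    reference_length_px: float

    def __post_init__(self) -> None:
        if self.reference_length_um <= 0 or self.reference_length_px <= 0:
            raise MorphometryError("reference lengths must be strictly positive")

    @property
    def um_per_px(self) -> float:
        return self.reference_length_um / self.reference_length_px

    @classmethod
    def from_um_per_px(cls, um_per_px: float) -> "CalibrationScale":
        if um_per_px <= 0:
            raise MorphometryError("um_per_px must be strictly positive")
        return cls(reference_length_um=um_per_px, reference_length_px=1.0)


def _signed_area_px(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass(frozen=True, eq=False)
class Contour:
    """Closed simple polygon in pixel coordinates.

    ``points`` is an (N, 2) float array of (x, y) vertices, implicitly
    closed. On construction the contour is validated (≥3 distinct
    vertices, nonzero area, simple) and re-oriented counter-clockwise.
    Set ``check_simple=False`` to skip the (shapely-based) simplicity
    check for contours already known to be simple, e.g. marching-squares
    output.
    """

    points: np.ndarray

    def __init__(self, points: Iterable, check_simple: bool = True) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DegenerateContourError("contour points must be an (N, 2) array")
        # drop an explicitly repeated closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise DegenerateContourError("contour needs at least 3 points")
        area = _signed_area_px(pts)
        if abs(area) < 1e-12:
            raise DegenerateContourError("degenerate (collinear) contour: zero area")
        if area < 0:
            pts = pts[::-1]
        if check_simple and not _ShapelyPolygon(pts).is_valid:
            raise DegenerateContourError("self-intersecting contour")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Contour):
            return NotImplemented
        return np.array_equal(self.points, other.points)

    def __hash__(self) -> int:
        return hash(self.points.tobytes())

    def area_px(self) -> float:
        """Shoelace area in px² (always positive: CCW-normalized)."""
        return _signed_area_px(self.points)

    def perimeter_px(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> tuple[float, float]:
        c = _ShapelyPolygon(self.points).centroid
        return (c.x, c.y)

    def transformed(self, fn) -> "Contour":
        """New contour with ``fn`` applied to the (N, 2) point array."""
        return Contour(fn(self.points.copy()), check_simple=False)


@dataclass(frozen=True)
class ShapeMeasures:
    """Calibrated descriptors of one closed shape (all μm-based)."""

    area: float
    perimeter: float
    circularity: float
    height: float
    width: float

    def __post_init__(self) -> None:
        for name in ("area", "perimeter", "height", "width"):
            if getattr(self, name) <= 0:
                raise MorphometryError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class FiberMetrics:
    """The full per-fiber record: raw shape measures plus derived traits."""

    name: str
    lumen: ShapeMeasures
    outer: ShapeMeasures
    outer_true_area: float
    outer_lumen_ratio: float
    theta: float
    fineness: float
    maturity_ratio: float
    standard_fineness: float
    line: str


def polygon_area(contour: Contour, scale: CalibrationScale) -> float:
    """Shoelace polygon area in μm² (pixel area × um_per_px²)."""
    return contour.area_px() * scale.um_per_px**2


def polygon_perimeter(contour: Contour, scale: CalibrationScale) -> float:
    """Closed polyline arc length in μm."""
    return contour.perimeter_px() * scale.um_per_px


def circularity(area: float, perimeter: float) -> float:
    """4π·A/P²: 1 for a circle, < 1 for anything else."""
    if area <= 0 or perimeter <= 0:
        raise MorphometryError("area and perimeter must be strictly positive")
    return 4.0 * math.pi * area / perimeter**2


def bounding_dims(contour: Contour, scale: CalibrationScale) -> tuple[float, float]:
    """Axis-aligned (height, width) in μm — height along y, width along x."""
    lo = contour.points.min(axis=0)
    hi = contour.points.max(axis=0)
    width = (hi[0] - lo[0]) * scale.um_per_px
    height = (hi[1] - lo[1]) * scale.um_per_px
    return (height, width)


def measure_shape(contour: Contour, scale: CalibrationScale) -> ShapeMeasures:
    """All five shape descriptors of one contour."""
    a = polygon_area(contour, scale)
    p = polygon_perimeter(contour, scale)
    h, w = bounding_dims(contour, scale)
    return ShapeMeasures(area=a, perimeter=p, circularity=circularity(a, p), height=h, width=w)


def theta_of(outer_true_area: float, outer_perimeter: float) -> float:
    """Degree of cell-wall thickening, 4π·A_true/P_outer²."""
    if outer_true_area <= 0 or outer_perimeter <= 0:
        raise MorphometryError("theta needs positive wall area and outer perimeter")
    return 4.0 * math.pi * outer_true_area / outer_perimeter**2


def fineness_of(outer_true_area: float, density: float = COTTON_DENSITY_G_CM3) -> float:
    """Linear density in millitex: wall area (μm²) × fiber density (g/cm³)."""
    if outer_true_area <= 0:
        raise MorphometryError("fineness needs positive wall area")
    return density * outer_true_area


def maturity_ratio_of(theta: float) -> float:
    """θ normalized by the standard-maturity reference value 0.577."""
    if theta <= 0:
        raise MorphometryError("theta must be strictly positive")
    return theta / STANDARD_MATURITY_THETA


def standard_fineness_of(fineness: float, theta: float) -> float:
    """Fineness rescaled to standard maturity: 0.577·F/θ."""
    if fineness <= 0 or theta <= 0:
        raise MorphometryError("fineness and theta must be strictly positive")
    return STANDARD_MATURITY_THETA * fineness / theta


def derive_fiber_metrics(
    lumen: ShapeMeasures,
    outer: ShapeMeasures,
    name: str = "",
    line: str = "",
) -> FiberMetrics:
    """Assemble the full metric record from lumen and outer measures.

    ``outer.area`` is the whole-fiber area *including* the lumen; the
    wall area is recovered by subtraction. Raises
    :class:`MorphometryError` when the lumen is not strictly smaller
    than the fiber.
    """
    if lumen.area >= outer.area:
        raise MorphometryError(
            f"lumen exceeds fiber: lumen area {lumen.area:g} ≥ outer area {outer.area:g}"
        )
    a_true = outer.area - lumen.area
    theta = theta_of(a_true, outer.perimeter)
    fineness = fineness_of(a_true)
    return FiberMetrics(
        name=name,
        lumen=lumen,
        outer=outer,
        outer_true_area=a_true,
        outer_lumen_ratio=a_true / lumen.area,
        theta=theta,
        fineness=fineness,
        maturity_ratio=maturity_ratio_of(theta),
        standard_fineness=standard_fineness_of(fineness, theta),
        line=line,
    )
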