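"""Shared containers for short-axis cine LV quantification.

Geometry conventions
--------------------
Images are stored as ``(n_slices, n_rows, n_cols)`` arrays. In-plane
coordinates are planar millimetres with the origin at the grid corner,
``x`` increasing column-wise and ``y`` increasing row-wise; the centre of
voxel ``(row r, col c)`` sits at ``((c + 0.5) * dx, (r + 0.5) * dx)``.
Contours are open vertex lists (the closing edge is implicit); the JSON
interchange dialect writes them closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

ED = "ED"
ES = "ES"

MYOCARDIAL_DENSITY_G_PER_ML = 1.05
"""Myocardial tissue density used to convert muscle volume to mass."""


class CmrSportError(Exception):
    """Base class for package errors."""


class ValidationError(CmrSportError, ValueError):
    """Invalid input values or inconsistent geometry."""


class GeometryError(ValidationError):
    """Requested geometry does not fit the voxel grid."""


class MethodRequirementError(CmrSportError):
    """A quantification method is missing a required input (e.g. contour)."""


class DegenerateHistogramError(CmrSportError):
    """Intensity histogram has no usable two-class structure."""


class FormatError(CmrSportError):
    """Unreadable or underspecified interchange file."""


def polygon_area(vertices: np.ndarray) -> float:
    """Area of a simple polygon by the shoelace formula (mm^2).

    ``vertices`` is an ``(n, 2)`` array; the closing edge is implicit.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def as_polygon(vertices: np.ndarray) -> Polygon:
    poly = Polygon(np.asarray(vertices, dtype=float))
    if not poly.is_valid:
        raise ValidationError("polygon is self-intersecting or otherwise invalid")
    return poly


def points_in_polygon(vertices: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside the polygon (voxel-center test)."""
    poly = as_polygon(vertices)
    shapely.prepare(poly)
    return shapely.contains_xy(poly, xs, ys)


@dataclass
class SliceContours:
    """Endocardial (optional) and epicardial polygons for one slice, mm."""

    epi: np.ndarray
    endo: np.ndarray | None = None

    def validate(self) -> None:
        epi = as_polygon(self.epi)
        if self.endo is not None:
            endo = as_polygon(self.endo)
            if not shapely.contains_properly(epi, endo):
                raise ValidationError("endocardial contour must lie strictly inside the epicardial contour")


@dataclass
class ContourSet:
    """Per-phase, per-slice contour polygons.

    ``phases`` maps a phase label (``"ED"``/``"ES"``) to a mapping from
    slice index to :class:`SliceContours`.
    """

    phases: dict[str, dict[int, SliceContours]]

    def slice_indices(self, phase: str) -> list[int]:
        return sorted(self.phases[phase])

    def validate(self) -> None:
        for per_slice in self.phases.values():
            for sc in per_slice.values():
                sc.validate()


@dataclass
class ShortAxisStack:
    """Short-axis cine stack: one 3-D intensity grid per cardiac phase.

    All phases share the voxel geometry. ``slice_gap`` defaults to zero
    (contiguous 8 mm slices are the usual acquisition).
    """

    phases: dict[str, np.ndarray]
    in_plane_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise ValidationError("voxel spacing must be positive")
        if self.slice_gap < 0:
            raise ValidationError("slice gap cannot be negative")
        shapes = {a.shape for a in self.phases.values()}
        if len(shapes) > 1:
            raise ValidationError("all phases must share the grid shape")

    @property
    def n_slices(self) -> int:
        return next(iter(self.phases.values())).shape[0]

    @property
    def slab_thickness(self) -> float:
        """Through-plane extent represented by one slice (mm)."""
        return self.slice_thickness + self.slice_gap

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_spacing**2 * self.slab_thickness

    def voxel_center_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened in-plane voxel-centre coordinates (x_mm, y_mm)."""
        _, ny, nx = next(iter(self.phases.values())).shape
        dx = self.in_plane_spacing
        xs = (np.arange(nx) + 0.5) * dx
        ys = (np.arange(ny) + 0.5) * dx
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()
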