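"""End-diastolic wall thickness perpendicular to the myocardial centerline.

The centerline is the closed mid-wall curve obtained by matching
endocardial and epicardial boundary points along rays from the cavity
centroid. Thickness is measured per centerline sample as the length of
the chord through the sample, perpendicular to the local centerline
tangent, clipped to the connected compact-wall crossing that contains
the sample — so the chord never traverses the cavity or the opposite
wall, and trabeculae/papillary muscles (inside the endocardial contour)
never contribute.

The maximal EDWT is taken over all slices and samples; the minimal EDWT
is taken within the slice of the maximum, as is conventional for the
max/min wall-thickness ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .core import ContourSet, ED, ValidationError, as_polygon

DEFAULT_N_CHORDS = 360  # 1 degree sampling, well below the voxel limit
SKIP_WARNING_FRACTION = 0.10


@dataclass
class WallThicknessResult:
    """Wall-thickness summary of the end-diastolic phase (mm)."""

    max_edwt: float
    min_edwt: float
    slice_of_max: int
    thickness_profile: np.ndarray  # (n_slices, n_chords), NaN where skipped
    slice_indices: list[int]
    n_skipped: int
    warning: bool

    @property
    def max_min_ratio(self) -> float:
        return self.max_edwt / self.min_edwt


def _ray_boundary_point(boundary, centroid: Point, direction: np.ndarray, reach: float) -> Point | None:
    """First crossing of the ray from the centroid with a polygon boundary."""
    tip = (centroid.x + reach * direction[0], centroid.y + reach * direction[1])
    hit = LineString([ (centroid.x, centroid.y), tip ]).intersection(boundary)
    if hit.is_empty:
        return None
    points: list[Point] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            points.append(geom)
        else:  # rare collinear overlap; use its endpoints
            points.extend(Point(c) for c in geom.coords)
    return min(points, key=centroid.distance)


def myocardial_centerline(
    endo: np.ndarray, epi: np.ndarray, n_samples: int = DEFAULT_N_CHORDS
) -> tuple[np.ndarray, np.ndarray]:
    """Closed mid-wall curve with unit tangents.

    Point ``i`` is the midpoint of the endocardial and epicardial
    boundary points met by the ray from the cavity centroid at angle
    ``2*pi*i/n_samples``; tangents come from central differences over
    the closed sequence.
    """
    if n_samples < 16:
        raise ValidationError("n_samples must be at least 16")
    endo_poly = as_polygon(endo)
    epi_poly = as_polygon(epi)
    if not shapely.contains_properly(epi_poly, endo_poly):
        raise ValidationError("endocardial contour must lie strictly inside the epicardial contour")
    centroid = endo_poly.centroid
    reach = 4.0 * max(np.ptp(np.asarray(epi)[:, 0]), np.ptp(np.asarray(epi)[:, 1]))
    angles = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    points = np.empty((n_samples, 2))
    for i, ang in enumerate(angles):
        direction = np.array([np.cos(ang), np.sin(ang)])
        p_endo = _ray_boundary_point(endo_poly.exterior, centroid, direction, reach)
        p_epi = _ray_boundary_point(epi_poly.exterior, centroid, direction, reach)
        if p_endo is None or p_epi is None:
            raise ValidationError("ray from cavity centroid failed to cross both contours")
        points[i] = 0.5 * np.array([p_endo.x + p_epi.x, p_endo.y + p_epi.y])
    tangents = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("degenerate centerline (coincident samples)")
    return points, tangents / norms


def _chord_thickness(wall: Polygon, point: np.ndarray, normal: np.ndarray, reach: float) -> float | None:
    """Length of the compact-wall crossing containing the sample point."""
    chord = LineString([point - reach * normal, point + reach * normal])
    hit = chord.intersection(wall)
    if hit.is_empty:
        return None
    p = Point(point)
    best, best_dist = None, np.inf
    for geom in getattr(hit, "geoms", [hit]):
        if not isinstance(geom, LineString):
            continue
        d = geom.distance(p)
        if d < best_dist:
            best, best_dist = geom, d
    if best is None or best_dist > 1e-6:
        return None  # sample not on any wall crossing
    return float(best.length)


def measure_edwt(contours: ContourSet, n_chords: int = DEFAULT_N_CHORDS, phase: str = ED) -> WallThicknessResult:
    """Maximal/minimal end-diastolic wall thickness over all slices.

    Chords failing to produce a compact-wall crossing are skipped and
    counted; more than 10% skipped sets the warning flag.
    """
    per_slice = contours.phases.get(phase)
    if not per_slice:
        raise ValidationError(f"no contours for phase {phase!r}")
    slice_indices = sorted(per_slice)
    profile = np.full((len(slice_indices), n_chords), np.nan)
    n_skipped = 0
    for row, idx in enumerate(slice_indices):
        sc = per_slice[idx]
        if sc.endo is None:
            raise ValidationError(f"slice {idx}: endocardial contour required for wall thickness")
        points, tangents = myocardial_centerline(sc.endo, sc.epi, n_chords)
        wall = Polygon(np.asarray(sc.epi, dtype=float), holes=[np.asarray(sc.endo, dtype=float)])
        if not wall.is_valid:
            raise ValidationError(f"slice {idx}: invalid wall annulus")
        shapely.prepare(wall)
        reach = 4.0 * max(np.ptp(np.asarray(sc.epi)[:, 0]), np.ptp(np.asarray(sc.epi)[:, 1]))
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        for j in range(n_chords):
            t = _chord_thickness(wall, points[j], normals[j], reach)
            if t is None:
                n_skipped += 1
            else:
                profile[row, j] = t
    if np.all(np.isnan(profile)):
        raise ValidationError("no valid wall-thickness chords on any slice")
    flat_max = np.nanmax(profile, axis=1)
    row_of_max = int(np.nanargmax(flat_max))
    max_edwt = float(flat_max[row_of_max])
    min_edwt = float(np.nanmin(profile[row_of_max]))
    if min_edwt <= 0:
        raise ValidationError("non-positive wall thickness measured")
    total = profile.size
    return WallThicknessResult(
        max_edwt=max_edwt,
        min_edwt=min_edwt,
        slice_of_max=slice_indices[row_of_max],
        thickness_profile=profile,
        slice_indices=slice_indices,
        n_skipped=n_skipped,
        warning=n_skipped > SKIP_WARNING_FRACTION * total,
    )
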