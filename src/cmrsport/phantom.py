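"""Voxelized left-ventricular phantoms with analytic ground truth.

The phantom is a stack of short-axis slices, each an annulus of compact
myocardium around a bright blood pool. The wall thickness varies with
angle as

    t(theta) = wall_base + wall_bump_amplitude * exp((cos(theta - c) - 1) / w**2)

a von-Mises-shaped bump that emulates asymmetric septal thickening; with
zero amplitude the phantom is a uniform annulus. Trabeculae are radial
ridges occupying a prescribed fraction of a thin ring just inside the
endocardial border, and papillary muscles are two cylinders placed at
+/-60 degrees from the bump centre in the central 40% of slices. Both
are dark (muscle intensity) structures inside the smooth endocardial
contour, so a contour-based method counts them in the blood pool while
an intensity-threshold method counts them as mass.

Images are rendered on a supersampled grid and block-averaged down to
the acquisition grid, producing partial-volume intermediate intensities
at every tissue interface; Gaussian noise is then added at acquisition
resolution. Ground truth is counted on the supersampled grid and never
touches the quantification code under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ED,
    ES,
    ContourSet,
    GeometryError,
    ShortAxisStack,
    SliceContours,
    ValidationError,
)

TRAB_RING_DEPTH_MM = 3.0
N_TRAB_RIDGES = 8
PAPILLARY_CENTER_FRACTION = 0.55  # of the endocardial radius
PAPILLARY_SLICE_FRACTION = 0.4
PAPILLARY_ANGLE_OFFSET = math.pi / 3

_CLASS_BG, _CLASS_BLOOD, _CLASS_COMPACT, _CLASS_TPM = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Geometry, intensity and sampling parameters of one phantom."""

    n_slices: int = 10
    slice_thickness: float = 8.0
    in_plane_spacing: float = 1.0
    grid_size: int = 128
    endo_radius_ed: float = 25.0
    endo_radius_es: float = 18.0
    wall_base: float = 10.0
    wall_bump_amplitude: float = 0.0
    wall_bump_center: float = math.pi / 2
    wall_bump_width: float = 0.6
    n_papillary: int = 2
    papillary_radius: float = 5.0
    trabecular_fraction: float = 0.0
    blood_intensity: float = 1000.0
    muscle_intensity: float = 200.0
    noise_sigma: float = 0.0
    supersampling_factor: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.wall_base <= 0:
            raise ValidationError("wall_base must be positive")
        if self.wall_bump_amplitude < 0:
            raise ValidationError("wall_bump_amplitude cannot be negative")
        if self.wall_bump_amplitude > 0 and self.wall_bump_width <= 0:
            raise ValidationError("wall_bump_width must be positive when a bump is present")
        if self.blood_intensity <= self.muscle_intensity:
            raise ValidationError("blood intensity must exceed muscle intensity")
        if not (self.endo_radius_ed > self.endo_radius_es > 0):
            raise ValidationError("need endo_radius_ed > endo_radius_es > 0")
        if not (0.0 <= self.trabecular_fraction <= 0.3):
            raise ValidationError("trabecular_fraction must lie in [0, 0.3]")
        if self.supersampling_factor < 1:
            raise ValidationError("supersampling_factor must be >= 1")
        if self.n_slices < 1 or self.grid_size < 8:
            raise ValidationError("need at least one slice and an 8-voxel grid")
        if self.n_papillary not in (0, 1, 2):
            raise ValidationError("n_papillary must be 0, 1 or 2")
        half_extent = 0.5 * self.grid_size * self.in_plane_spacing
        max_epi = self.endo_radius_ed + self.wall_base + self.wall_bump_amplitude
        if max_epi + self.in_plane_spacing > half_extent:
            raise GeometryError(
                f"epicardial radius {max_epi:.1f} mm does not fit a "
                f"{self.grid_size}-voxel grid at {self.in_plane_spacing} mm spacing"
            )

    def wall_thickness(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Analytic wall thickness t(theta) in mm."""
        if self.wall_bump_amplitude == 0:
            return self.wall_base + np.zeros_like(np.asarray(theta, dtype=float))
        kern = np.exp(
            (np.cos(np.asarray(theta, dtype=float) - self.wall_bump_center) - 1.0)
            / self.wall_bump_width**2
        )
        return self.wall_base + self.wall_bump_amplitude * kern


@dataclass
class PhantomTruth:
    """Ground truth counted on the supersampled grid (volumes in ml, mm)."""

    cavity_volume_ed: float
    cavity_volume_es: float
    compact_myo_volume: float
    tpm_volume: float
    max_wall_thickness: float
    min_wall_thickness_same_slice: float
    slice_of_max: int
    thickness_angles: np.ndarray
    thickness_field: np.ndarray  # (n_slices, n_angles), mm
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    subvoxel_volume_mm3: float = 0.0


def _papillary_centers(spec: PhantomSpec, endo_radius: float) -> list[tuple[float, float]]:
    rc = PAPILLARY_CENTER_FRACTION * endo_radius
    offsets = {0: [], 1: [PAPILLARY_ANGLE_OFFSET], 2: [PAPILLARY_ANGLE_OFFSET, -PAPILLARY_ANGLE_OFFSET]}
    return [
        (rc * math.cos(spec.wall_bump_center + off), rc * math.sin(spec.wall_bump_center + off))
        for off in offsets[spec.n_papillary]
    ]


def _classify_plane(spec: PhantomSpec, endo_radius: float, with_papillary: bool) -> np.ndarray:
    """Tissue-class map of one slice plane on the supersampled grid."""
    n = spec.grid_size * spec.supersampling_factor
    step = spec.in_plane_spacing / spec.supersampling_factor
    center = 0.5 * spec.grid_size * spec.in_plane_spacing
    coords = (np.arange(n) + 0.5) * step - center
    x, y = np.meshgrid(coords, coords)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    epi_r = endo_radius + spec.wall_thickness(theta)
    inside_endo = r <= endo_radius
    compact = (r > endo_radius) & (r <= epi_r)

    tpm = np.zeros_like(inside_endo)
    if spec.trabecular_fraction > 0:
        ring = inside_endo & (r >= endo_radius - TRAB_RING_DEPTH_MM)
        ridge_phase = np.mod((theta - spec.wall_bump_center) * N_TRAB_RIDGES / (2 * math.pi), 1.0)
        tpm |= ring & (ridge_phase < spec.trabecular_fraction)
    if with_papillary and spec.n_papillary > 0:
        for cx, cy in _papillary_centers(spec, endo_radius):
            tpm |= inside_endo & (np.hypot(x - cx, y - cy) <= spec.papillary_radius)

    classes = np.zeros((n, n), dtype=np.uint8)
    classes[compact] = _CLASS_COMPACT
    classes[inside_endo & ~tpm] = _CLASS_BLOOD
    classes[tpm] = _CLASS_TPM
    return classes


def _render_plane(spec: PhantomSpec, classes: np.ndarray) -> np.ndarray:
    """Block-average a supersampled class map into acquisition intensities."""
    intensity = np.zeros(classes.shape, dtype=float)
    intensity[classes == _CLASS_BLOOD] = spec.blood_intensity
    intensity[(classes == _CLASS_COMPACT) | (classes == _CLASS_TPM)] = spec.muscle_intensity
    k = spec.supersampling_factor
    g = spec.grid_size
    return intensity.reshape(g, k, g, k).mean(axis=(1, 3))


def _papillary_slice_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros(spec.n_slices, dtype=bool)
    if spec.n_papillary > 0:
        n_pap = max(1, round(PAPILLARY_SLICE_FRACTION * spec.n_slices))
        start = (spec.n_slices - n_pap) // 2
        mask[start : start + n_pap] = True
    return mask


def _circle_polygon(radius: float, center: float, n_vertices: int) -> np.ndarray:
    ang = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([center + radius * np.cos(ang), center + radius * np.sin(ang)])


def _epi_polygon(spec: PhantomSpec, endo_radius: float, n_vertices: int) -> np.ndarray:
    center = 0.5 * spec.grid_size * spec.in_plane_spacing
    ang = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    r = endo_radius + np.asarray(spec.wall_thickness(ang))
    return np.column_stack([center + r * np.cos(ang), center + r * np.sin(ang)])


def _contour_vertex_count(radius: float, spacing: float) -> int:
    # vertex arc step tracks the image resolution, like contours drawn on it
    return max(64, int(math.ceil(2 * math.pi * radius / spacing)))


def generate_phantom(spec: PhantomSpec) -> tuple[ShortAxisStack, ContourSet, PhantomTruth]:
    """Render a two-phase phantom with contours and supersampled ground truth.

    Returns the image stack (phases ``ED`` and ``ES``), the contour set
    (endocardial contour = smooth cavity boundary, trabeculae and
    papillary muscles inside it; epicardial contour around the compact
    wall) and the :class:`PhantomTruth`. Identical specs (including the
    seed) give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pap_slices = _papillary_slice_mask(spec)
    sub_volume = (spec.in_plane_spacing / spec.supersampling_factor) ** 2 * spec.slice_thickness

    phases: dict[str, np.ndarray] = {}
    contours: dict[str, dict[int, SliceContours]] = {}
    class_counts: dict[str, dict[str, int]] = {}
    endo_radii = {ED: spec.endo_radius_ed, ES: spec.endo_radius_es}

    for phase, endo_radius in endo_radii.items():
        plain = _classify_plane(spec, endo_radius, with_papillary=False)
        with_pap = _classify_plane(spec, endo_radius, with_papillary=True) if pap_slices.any() else plain
        images = {False: _render_plane(spec, plain), True: _render_plane(spec, with_pap)}
        stack = np.stack([images[bool(pap_slices[i])] for i in range(spec.n_slices)])
        if spec.noise_sigma > 0:
            stack = stack + rng.normal(0.0, spec.noise_sigma, size=stack.shape)
        phases[phase] = stack

        counts = {"blood": 0, "compact": 0, "tpm": 0}
        for classes, n_rep in ((plain, int((~pap_slices).sum())), (with_pap, int(pap_slices.sum()))):
            if n_rep == 0:
                continue
            counts["blood"] += n_rep * int((classes == _CLASS_BLOOD).sum())
            counts["compact"] += n_rep * int((classes == _CLASS_COMPACT).sum())
            counts["tpm"] += n_rep * int((classes == _CLASS_TPM).sum())
        class_counts[phase] = counts

        center = 0.5 * spec.grid_size * spec.in_plane_spacing
        endo_poly = _circle_polygon(
            endo_radius, center, _contour_vertex_count(endo_radius, spec.in_plane_spacing)
        )
        epi_poly = _epi_polygon(
            spec,
            endo_radius,
            _contour_vertex_count(endo_radius + spec.wall_base, spec.in_plane_spacing),
        )
        contours[phase] = {
            i: SliceContours(epi=epi_poly.copy(), endo=endo_poly.copy())
            for i in range(spec.n_slices)
        }

    angles = np.linspace(0.0, 2 * math.pi, 720, endpoint=False)
    profile = np.asarray(spec.wall_thickness(angles), dtype=float)
    thickness_field = np.tile(profile, (spec.n_slices, 1))
    slice_of_max = 0  # cross-section identical on every slice; ties go basally

    truth = PhantomTruth(
        cavity_volume_ed=class_counts[ED]["blood"] * sub_volume / 1000.0,
        cavity_volume_es=class_counts[ES]["blood"] * sub_volume / 1000.0,
        compact_myo_volume=class_counts[ED]["compact"] * sub_volume / 1000.0,
        tpm_volume=class_counts[ED]["tpm"] * sub_volume / 1000.0,
        max_wall_thickness=float(profile.max()),
        min_wall_thickness_same_slice=float(profile.min()),
        slice_of_max=slice_of_max,
        thickness_angles=angles,
        thickness_field=thickness_field,
        class_counts=class_counts,
        subvoxel_volume_mm3=sub_volume,
    )
    stack = ShortAxisStack(
        phases=phases,
        in_plane_spacing=spec.in_plane_spacing,
        slice_thickness=spec.slice_thickness,
        slice_gap=0.0,
    )
    return stack, ContourSet(phases=contours), truth


def athlete_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom emulating an endurance athlete's LV: large cavity, mild
    near-symmetric wall, modest trabeculation."""
    params = dict(
        endo_radius_ed=30.6,
        endo_radius_es=20.0,
        wall_base=7.0,
        wall_bump_amplitude=5.6,
        wall_bump_width=0.5,
        trabecular_fraction=0.12,
        noise_sigma=20.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def hcm_like_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom emulating hypertrophic cardiomyopathy: smaller cavity,
    strongly asymmetric thick wall, pronounced trabeculation."""
    params = dict(
        endo_radius_ed=25.0,
        endo_radius_es=15.5,
        wall_base=8.0,
        wall_bump_amplitude=14.0,
        wall_bump_width=0.8,
        trabecular_fraction=0.20,
        noise_sigma=20.0,
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)
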