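"""Left-ventricular quantification from short-axis cine stacks.

Two methods are implemented, mirroring routine CMR post-processing:

* **CQ** (conventional, contour-based): cavity volume from the
  endocardial polygon area on every slice, so trabeculae and papillary
  muscles (TPM) are counted in the blood pool; myocardial mass from the
  epi-minus-endo annulus at end-diastole.
* **TQ** (threshold-based): every voxel inside the epicardial contour is
  classified as blood or muscle by a signal-intensity cut placed at a
  fixed fraction (default 50%) between per-slice blood and muscle
  intensity estimates. TPM are the muscle voxels inside the endocardial
  contour; they join the myocardial mass and leave the blood pool.

Volumes use slice summation (area x slab thickness); masses use a
myocardial density of 1.05 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .core import (
    ED,
    ES,
    MYOCARDIAL_DENSITY_G_PER_ML,
    ContourSet,
    DegenerateHistogramError,
    MethodRequirementError,
    ShortAxisStack,
    ValidationError,
    points_in_polygon,
    polygon_area,
)

DEFAULT_THRESHOLD_FRACTION = 0.5


@dataclass
class LabelMap:
    """Voxel classification of one phase inside the epicardial mask.

    ``blood``/``muscle`` partition the epicardial mask; ``tpm`` is the
    muscle inside the endocardial contour, ``compact`` the muscle
    outside it. ``cavity_blood`` collects every blood-labelled voxel.
    """

    epi_mask: np.ndarray
    blood: np.ndarray
    muscle: np.ndarray
    tpm: np.ndarray
    compact: np.ndarray
    per_slice_cuts: np.ndarray

    @property
    def cavity_blood(self) -> np.ndarray:
        return self.blood


@dataclass
class VolumetricResult:
    """Volumes (ml), ejection fraction (%) and masses (g) of one method."""

    method: str  # "CQ" or "TQ"
    lvedv: float
    lvesv: float
    lvm: float
    tpm_mass: float | None = None
    slice_areas: dict[str, np.ndarray] | None = None  # cm^2 per phase

    @property
    def lvsv(self) -> float:
        return self.lvedv - self.lvesv

    @property
    def lvef(self) -> float:
        return 100.0 * self.lvsv / self.lvedv

    def __post_init__(self) -> None:
        if min(self.lvedv, self.lvesv, self.lvm) < 0:
            raise ValidationError("volumes and masses must be non-negative")


def slice_summation_volume(areas_mm2, slice_thickness: float, slice_gap: float = 0.0) -> float:
    """Volume in ml by slice summation: sum(area_i) x slab thickness.

    The slab assigned to each slice spans the slice thickness plus the
    interslice gap (zero for contiguous acquisitions).
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size and areas.min() < 0:
        raise ValidationError("slice areas must be non-negative")
    if slice_thickness <= 0 or slice_gap < 0:
        raise ValidationError("invalid slice geometry")
    return float(areas.sum() * (slice_thickness + slice_gap) / 1000.0)


def _phase_labels(stack: ShortAxisStack, contours: ContourSet) -> tuple[str, str]:
    """Return (ED, ES) phase labels; derive them from CQ cavity volume
    when the stack is not already labelled ED/ES."""
    labels = set(stack.phases)
    if {ED, ES} <= labels:
        return ED, ES
    volumes = {}
    for label in stack.phases:
        per_slice = contours.phases.get(label, {})
        areas = [polygon_area(sc.endo) for sc in per_slice.values() if sc.endo is not None]
        if not areas:
            raise MethodRequirementError(f"phase {label!r}: endocardial contours required to identify ED/ES")
        volumes[label] = sum(areas)
    ed = max(volumes, key=volumes.get)
    es = min(volumes, key=volumes.get)
    return ed, es


def cq_quantify(
    stack: ShortAxisStack,
    contours: ContourSet,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> VolumetricResult:
    """Conventional contour-based quantification.

    Cavity volumes come from endocardial polygon areas (shoelace
    formula), so TPM stay in the blood pool; LVM is the end-diastolic
    epi-minus-endo annulus volume times density.
    """
    ed, es = _phase_labels(stack, contours)
    cavity = {}
    slice_areas = {}
    for phase in (ed, es):
        areas = []
        for idx in contours.slice_indices(phase):
            sc = contours.phases[phase][idx]
            if sc.endo is None:
                raise MethodRequirementError(
                    f"CQ needs an endocardial contour on every slice (phase {phase}, slice {idx})"
                )
            areas.append(polygon_area(sc.endo))
        cavity[phase] = slice_summation_volume(areas, stack.slice_thickness, stack.slice_gap)
        slice_areas[phase] = np.asarray(areas) / 100.0  # cm^2

    annulus = [
        polygon_area(sc.epi) - polygon_area(sc.endo)
        for sc in (contours.phases[ed][i] for i in contours.slice_indices(ed))
    ]
    if min(annulus) < 0:
        raise ValidationError("epicardial contour smaller than endocardial contour")
    myo_volume = slice_summation_volume(annulus, stack.slice_thickness, stack.slice_gap)
    return VolumetricResult(
        method="CQ",
        lvedv=cavity[ed],
        lvesv=cavity[es],
        lvm=myo_volume * density,
        slice_areas=slice_areas,
    )


def estimate_class_intensities(values: np.ndarray) -> tuple[float, float]:
    """Estimate (blood, muscle) intensities from in-mask voxel values.

    A two-class Otsu split of the histogram yields the class means;
    blood is the brighter class. A flat or effectively one-class
    histogram raises :class:`DegenerateHistogramError` so the caller can
    fall back to estimates pooled over all slices.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateHistogramError("empty epicardial mask")
    if np.ptp(values) == 0:
        raise DegenerateHistogramError("all in-mask intensities are identical")
    cut = threshold_otsu(values)
    upper = values[values > cut]
    lower = values[values <= cut]
    if upper.size == 0 or lower.size == 0:
        raise DegenerateHistogramError("histogram split produced an empty class")
    return float(upper.mean()), float(lower.mean())


def threshold_labelmap(
    phase_image: np.ndarray,
    per_slice_contours: dict,
    spacing: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> LabelMap:
    """Classify in-mask voxels of one phase as blood or muscle.

    Per slice, the cut is ``muscle + f * (blood - muscle)`` with the
    intensity estimates of :func:`estimate_class_intensities`; voxels
    strictly above the cut are blood, the rest (ties included) muscle.
    Slices with a degenerate histogram fall back to global estimates
    pooled over all slices of the phase.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        # 1.0 is the all-muscle limit: the cut reaches the blood estimate
        # and the tie rule sends every in-mask voxel to muscle
        raise ValidationError("threshold_fraction must lie in (0, 1]")
    n_slices, ny, nx = phase_image.shape
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys)
    flat_x, flat_y = gx.ravel(), gy.ravel()

    epi_mask = np.zeros(phase_image.shape, dtype=bool)
    endo_mask = np.zeros(phase_image.shape, dtype=bool)
    for idx, sc in per_slice_contours.items():
        epi_mask[idx] = points_in_polygon(sc.epi, flat_x, flat_y).reshape(ny, nx)
        if sc.endo is not None:
            endo_mask[idx] = points_in_polygon(sc.endo, flat_x, flat_y).reshape(ny, nx)

    pooled = phase_image[epi_mask]
    global_estimates: tuple[float, float] | None
    try:
        global_estimates = estimate_class_intensities(pooled)
    except DegenerateHistogramError:
        global_estimates = None

    cuts = np.full(n_slices, np.nan)
    blood = np.zeros(phase_image.shape, dtype=bool)
    for idx in per_slice_contours:
        mask = epi_mask[idx]
        if not mask.any():
            continue
        try:
            b_est, m_est = estimate_class_intensities(phase_image[idx][mask])
        except DegenerateHistogramError:
            if global_estimates is None:
                raise
            b_est, m_est = global_estimates
        cut = m_est + threshold_fraction * (b_est - m_est)
        cuts[idx] = cut
        blood[idx] = mask & (phase_image[idx] > cut)

    muscle = epi_mask & ~blood
    tpm = muscle & endo_mask
    compact = muscle & ~endo_mask
    return LabelMap(
        epi_mask=epi_mask, blood=blood, muscle=muscle, tpm=tpm, compact=compact, per_slice_cuts=cuts
    )


def tq_quantify(
    stack: ShortAxisStack,
    contours: ContourSet,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> VolumetricResult:
    """Threshold-based quantification.

    Cavity volumes are the blood-labelled voxel volumes per phase; LVM
    is every muscle-labelled voxel at end-diastole (compact wall plus
    TPM) times density, with the TPM mass also reported separately.
    """
    ed, es = _phase_labels(stack, contours)
    for phase in (ed, es):
        for idx in contours.slice_indices(phase):
            if contours.phases[phase][idx].endo is None:
                raise MethodRequirementError(
                    "TQ needs endocardial contours for the TPM partition "
                    f"(phase {phase}, slice {idx})"
                )
    voxel_ml = stack.voxel_volume_mm3 / 1000.0
    labels = {
        phase: threshold_labelmap(
            stack.phases[phase], contours.phases[phase], stack.in_plane_spacing, threshold_fraction
        )
        for phase in (ed, es)
    }
    slice_areas = {
        phase: labels[phase].blood.sum(axis=(1, 2)) * stack.in_plane_spacing**2 / 100.0
        for phase in (ed, es)
    }
    return VolumetricResult(
        method="TQ",
        lvedv=float(labels[ed].blood.sum()) * voxel_ml,
        lvesv=float(labels[es].blood.sum()) * voxel_ml,
        lvm=float(labels[ed].muscle.sum()) * voxel_ml * density,
        tpm_mass=float(labels[ed].tpm.sum()) * voxel_ml * density,
        slice_areas=slice_areas,
    )
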