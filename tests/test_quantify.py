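"""CQ and TQ quantification: closed forms, oracles, method ordering."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from cmrsport import (
    ContourSet,
    ShortAxisStack,
    SliceContours,
    cq_quantify,
    estimate_class_intensities,
    slice_summation_volume,
    threshold_labelmap,
    tq_quantify,
)
from cmrsport.core import DegenerateHistogramError, MethodRequirementError, ValidationError

DENSITY = 1.05


def circle(radius, center, n=256):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center + radius * np.cos(ang), center + radius * np.sin(ang)])


def two_phase_contours(endo_ed, endo_es, epi, center, n_slices):
    phases = {}
    for phase, endo_r in (("ED", endo_ed), ("ES", endo_es)):
        phases[phase] = {
            i: SliceContours(epi=circle(epi, center), endo=circle(endo_r, center))
            for i in range(n_slices)
        }
    return ContourSet(phases=phases)


class TestSliceSummation:
    def test_single_slab(self):
        assert slice_summation_volume([1000.0], 8.0) == pytest.approx(8.0)

    def test_empty_sum_is_zero(self):
        assert slice_summation_volume([], 8.0) == 0.0

    def test_cylinder_closed_form(self):
        areas = [np.pi * 25.0**2] * 10
        assert slice_summation_volume(areas, 8.0) == pytest.approx(157.08, abs=0.01)

    def test_gap_extends_the_slab(self):
        assert slice_summation_volume([1000.0], 8.0, slice_gap=2.0) == pytest.approx(10.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            slice_summation_volume([-1.0], 8.0)


class TestConventionalQuantification:
    def test_annulus_mass_matches_closed_form(self, cylinder_phantom):
        _, stack, contours, _ = cylinder_phantom
        result = cq_quantify(stack, contours, DENSITY)
        expected_mass = np.pi * (35.0**2 - 25.0**2) * 80.0 * DENSITY / 1000.0  # 158.3 g
        assert result.lvm == pytest.approx(expected_mass, rel=0.01)
        assert result.lvedv == pytest.approx(np.pi * 25.0**2 * 80.0 / 1000.0, rel=0.01)

    def test_identical_phases_have_zero_stroke_volume(self):
        img = np.zeros((3, 16, 16))
        stack = ShortAxisStack(phases={"ED": img, "ES": img}, in_plane_spacing=4.0, slice_thickness=8.0)
        contours = two_phase_contours(20.0, 20.0, 28.0, 32.0, 3)
        result = cq_quantify(stack, contours)
        assert result.lvsv == 0.0
        assert result.lvef == 0.0

    def test_missing_endocardial_contour_rejected(self, cylinder_phantom):
        _, stack, contours, _ = cylinder_phantom
        broken = ContourSet(
            phases={
                phase: {
                    idx: SliceContours(epi=sc.epi, endo=None if idx == 0 else sc.endo)
                    for idx, sc in per_slice.items()
                }
                for phase, per_slice in contours.phases.items()
            }
        )
        with pytest.raises(MethodRequirementError):
            cq_quantify(stack, broken)


class TestIntensityEstimation:
    def test_two_level_histogram_recovered_exactly(self):
        values = np.array([1000.0] * 60 + [200.0] * 40)
        blood, muscle = estimate_class_intensities(values)
        assert blood == 1000.0
        assert muscle == 200.0

    def test_noisy_class_means_within_standard_error(self, rng):
        n = 4000
        values = np.concatenate([rng.normal(1000, 30, n), rng.normal(200, 30, n)])
        blood, muscle = estimate_class_intensities(values)
        bound = 3 * 30 / np.sqrt(n)
        assert abs(blood - 1000) < bound + 1.0  # Otsu tail clipping allowance
        assert abs(muscle - 200) < bound + 1.0

    def test_flat_histogram_flagged(self):
        with pytest.raises(DegenerateHistogramError):
            estimate_class_intensities(np.full(100, 7.0))


class TestThresholdLabelmap:
    def test_matches_per_voxel_brute_force(self, rng):
        """Label map equals exhaustive voxel-center classification for
        arbitrary threshold fractions on random grids."""
        n = 24
        spacing = 2.0
        center = n * spacing / 2
        contours = {
            0: SliceContours(epi=circle(20.0, center), endo=circle(13.0, center)),
            1: SliceContours(epi=circle(18.0, center), endo=circle(11.0, center)),
        }
        image = rng.uniform(0, 1000, size=(2, n, n))
        for frac in (0.25, 0.5, 0.8):
            lm = threshold_labelmap(image, contours, spacing, frac)
            for s, sc in contours.items():
                epi, endo = Polygon(sc.epi), Polygon(sc.endo)
                for r in range(n):
                    for c in range(n):
                        p = Point((c + 0.5) * spacing, (r + 0.5) * spacing)
                        in_epi = epi.contains(p)
                        assert lm.epi_mask[s, r, c] == in_epi
                        if not in_epi:
                            continue
                        expect_blood = image[s, r, c] > lm.per_slice_cuts[s]
                        assert lm.blood[s, r, c] == expect_blood
                        assert lm.muscle[s, r, c] == (not expect_blood)
                        assert lm.tpm[s, r, c] == ((not expect_blood) and endo.contains(p))

    def test_unit_threshold_labels_everything_muscle(self):
        """In the threshold -> 1 limit the cut reaches the blood estimate
        and the tie rule sends every in-mask voxel to muscle."""
        n, spacing, center = 32, 2.0, 32.0
        contours = {0: SliceContours(epi=circle(24.0, center), endo=circle(15.0, center))}
        xs = (np.arange(n) + 0.5) * spacing
        gx, gy = np.meshgrid(xs, xs)
        image = np.where(np.hypot(gx - center, gy - center) <= 15.0, 1000.0, 200.0)[None]
        lm = threshold_labelmap(image, contours, spacing, 1.0)
        assert not lm.blood.any()
        assert np.array_equal(lm.muscle, lm.epi_mask)

    def test_partition_conserves_inmask_voxels(self, trabeculated_phantom):
        _, stack, contours, _ = trabeculated_phantom
        lm = threshold_labelmap(stack.phases["ED"], contours.phases["ED"], stack.in_plane_spacing)
        assert np.array_equal(lm.blood | lm.muscle, lm.epi_mask)
        assert not (lm.blood & lm.muscle).any()
        assert np.array_equal(lm.tpm | lm.compact, lm.muscle)
        assert not (lm.tpm & lm.compact).any()


class TestThresholdQuantification:
    def test_recovers_supersampled_truth(self, trabeculated_phantom):
        _, stack, contours, truth = trabeculated_phantom
        result = tq_quantify(stack, contours, density=DENSITY)
        assert result.lvedv == pytest.approx(truth.cavity_volume_ed, rel=0.02)
        assert result.lvm == pytest.approx(
            (truth.compact_myo_volume + truth.tpm_volume) * DENSITY, rel=0.02
        )
        assert result.tpm_mass == pytest.approx(truth.tpm_volume * DENSITY, rel=0.05)

    def test_no_tpm_phantom_agrees_with_cq(self, cylinder_phantom):
        _, stack, contours, _ = cylinder_phantom
        tq = tq_quantify(stack, contours, density=DENSITY)
        cq = cq_quantify(stack, contours, DENSITY)
        assert tq.tpm_mass == pytest.approx(0.0, abs=0.5)
        assert tq.lvm == pytest.approx(cq.lvm, rel=0.02)
        assert tq.lvedv == pytest.approx(cq.lvedv, rel=0.02)

    def test_method_ordering_with_tpm(self, trabeculated_phantom):
        """TPM moves from blood pool (CQ) to mass (TQ): smaller cavity,
        larger mass, higher ejection fraction."""
        _, stack, contours, _ = trabeculated_phantom
        tq = tq_quantify(stack, contours, density=DENSITY)
        cq = cq_quantify(stack, contours, DENSITY)
        assert tq.lvedv < cq.lvedv
        assert tq.lvm > cq.lvm
        assert tq.lvef > cq.lvef
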