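"""ROC analysis, cut-off search, DeLong comparison, adjusted regression."""

import numpy as np
import pytest

from cmrsport import (
    adjusted_group_compare,
    confusion_metrics,
    delong_compare,
    optimal_cutoff,
    roc_curve,
    roc_with_cutoff,
)
from cmrsport.core import ValidationError


def brute_force_auc(values, labels):
    """All-pairs Mann-Whitney concordance with half credit for ties."""
    pos = values[labels]
    neg = values[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestConfusionMetrics:
    def test_lge_contingency_of_the_study(self):
        m = confusion_metrics(143, 0, 47, 108)
        assert round(m.ppv) == 100
        assert round(m.npv) == 70
        assert m.sensitivity == pytest.approx(100 * 143 / 190)

    def test_symmetric_split_gives_half_sensitivity(self):
        assert confusion_metrics(25, 3, 25, 10).sensitivity == pytest.approx(50.0)

    def test_no_false_positives_gives_full_ppv(self):
        assert confusion_metrics(10, 0, 5, 5).ppv == pytest.approx(100.0)

    def test_zero_denominator_flagged_undefined(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m.ppv is None
        assert "ppv" in m.undefined
        assert m.npv is not None

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(-1, 0, 0, 1)


class TestROC:
    def test_perfect_separation(self):
        report = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert report.auc == 1.0

    def test_identical_distributions_near_half(self, rng):
        values = rng.normal(size=4000)
        labels = np.arange(4000) % 2 == 0
        assert roc_curve(values, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_trapezoid_equals_all_pairs_oracle(self, rng):
        for _ in range(50):
            values = rng.integers(0, 8, size=20).astype(float)  # force ties
            labels = rng.integers(0, 2, size=20).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert roc_curve(values, labels).auc == pytest.approx(
                brute_force_auc(values, labels), abs=1e-12
            )

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60).astype(bool)
        a = roc_curve(values, labels).auc
        b = roc_curve(np.exp(3 * values), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_operating_arrays_monotone_along_thresholds(self, rng):
        values = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80).astype(bool)
        report = roc_curve(values, labels)
        assert np.all(np.diff(report.sensitivity) <= 1e-12)
        assert np.all(np.diff(report.specificity) >= -1e-12)

    def test_auc_agrees_with_reference_library(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(size=120)
        labels = rng.integers(0, 2, size=120).astype(bool)
        assert roc_curve(values, labels).auc == pytest.approx(
            roc_auc_score(labels, values), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1.0, 2.0], [1, 1])


class TestOptimalCutoff:
    def test_separated_classes_use_midpoint(self):
        report = roc_with_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert report.optimal_threshold == pytest.approx(6.5)
        assert report.optimum.correctly_classified == pytest.approx(100.0)

    def test_uninformative_index_gives_majority_fraction(self):
        report = roc_with_cutoff([5.0] * 7, [1, 1, 1, 1, 0, 0, 0])
        assert report.optimum.correctly_classified == pytest.approx(100 * 4 / 7)

    def test_optimum_beats_every_candidate_threshold(self, rng):
        """Exhaustive comparison: accuracy at the reported optimum is the
        maximum over all candidate thresholds."""
        for _ in range(20):
            values = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30).astype(bool)
            if labels.all() or not labels.any():
                continue
            report = optimal_cutoff(roc_curve(values, labels))
            best = report.optimum.correctly_classified
            for t in report.thresholds:
                pred = values > t
                acc = 100 * np.mean(pred == labels)
                assert best >= acc - 1e-9


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        values = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        cmp = delong_compare(values, values, labels)
        assert cmp.auc_difference == 0.0
        assert cmp.p_value == 1.0

    def test_monotone_transform_leaves_auc_unchanged(self, rng):
        values = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50).astype(bool)
        cmp = delong_compare(values, np.exp(values), labels)
        assert cmp.auc_difference == pytest.approx(0.0, abs=1e-12)

    def test_variance_matches_bootstrap(self, rng):
        """DeLong variance of the paired AUC difference agrees with a
        subject-resampling bootstrap."""
        n = 60
        signal = rng.normal(size=n)
        labels = signal + rng.normal(0, 1.2, n) > 0
        a = signal + rng.normal(0, 0.8, n)
        b = signal + rng.normal(0, 1.5, n)
        cmp = delong_compare(a, b, labels)

        n_boot = 10000
        diffs = np.empty(n_boot)
        kept = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.all() or not lab.any():
                continue
            diffs[kept] = brute_force_auc(a[idx], lab) - brute_force_auc(b[idx], lab)
            kept += 1
        boot_var = diffs[:kept].var(ddof=1)
        assert cmp.variance == pytest.approx(boot_var, rel=0.3)

    def test_unpaired_lengths_rejected(self, rng):
        with pytest.raises(ValidationError):
            delong_compare([1.0, 2.0], [1.0, 2.0, 3.0], [0, 1])


class TestAdjustedComparison:
    def test_orthogonal_covariates_reduce_to_raw_difference(self):
        n = 40
        age = np.tile(np.linspace(30, 60, n), 2)
        hr = np.tile(np.linspace(50, 90, n) ** 2 / 70.0, 2)  # not collinear with age
        group = np.array(["athlete"] * n + ["hcm"] * n)
        outcome = np.r_[np.full(n, 10.0), np.full(n, 14.0)] + 0.2 * age + 0.1 * hr
        res = adjusted_group_compare(outcome, group, age, hr)[0]
        assert res.estimate == pytest.approx(4.0, abs=1e-9)
        assert res.groups == ("athlete", "hcm")

    def test_perfect_separation_gives_vanishing_p(self, rng):
        n = 60
        group = np.array(["a"] * n + ["b"] * n)
        age = rng.normal(45, 8, 2 * n)
        hr = rng.normal(65, 10, 2 * n)
        outcome = (group == "b").astype(float) + rng.normal(0, 1e-6, 2 * n)
        res = adjusted_group_compare(outcome, group, age, hr)[0]
        assert res.p_value < 1e-12

    def test_recovers_known_group_effect(self, rng):
        n = 200
        group = np.array(["athlete"] * n + ["hcm"] * n)
        age = rng.normal(40, 10, 2 * n)
        hr = rng.normal(60, 8, 2 * n)
        outcome = 5.0 * (group == "hcm") + 0.1 * age + 0.05 * hr + rng.normal(0, 1, 2 * n)
        res = adjusted_group_compare(outcome, group, age, hr)[0]
        assert abs(res.estimate - 5.0) < 3 * res.standard_error
        assert res.covariates == ("age", "heart_rate")

    def test_stratification_yields_one_result_per_stratum(self, rng):
        n = 30
        group = np.tile(np.array(["athlete"] * n + ["hcm"] * n), 2)
        strata = np.array(["M"] * 2 * n + ["F"] * 2 * n)
        age = rng.normal(40, 10, 4 * n)
        hr = rng.normal(60, 8, 4 * n)
        outcome = 2.0 * (group == "hcm") + rng.normal(0, 1, 4 * n)
        results = adjusted_group_compare(outcome, group, age, hr, strata=strata)
        assert [r.stratum for r in results] == ["F", "M"]

    def test_single_group_stratum_rejected(self, rng):
        with pytest.raises(ValidationError):
            adjusted_group_compare(
                rng.normal(size=10), ["a"] * 10, rng.normal(size=10), rng.normal(size=10)
            )
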