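"""Count-threshold ROC, Mann-Whitney AUC, DeLong CI, operating points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomdx import (
    EpidemiologicalMeasures,
    auc_curve,
    best_operating_point,
    delong_ci,
    roc_from_counts,
    simulate_cohort,
    single_symptom_auc,
)

count_vectors = st.lists(st.integers(0, 8), min_size=1, max_size=20)


def trapezoid_auc(roc):
    """Independent trapezoid integration of the empirical ROC.

    Integrates along the ROC path in threshold-decreasing order (FPR and
    TPR both non-decreasing), which keeps vertical segments at tied FPRs
    in the right order.
    """
    fpr = (1.0 - roc.specificities)[::-1]
    tpr = roc.sensitivities[::-1]
    return float(np.trapezoid(tpr, fpr))


def pairwise_auc(cases, controls):
    """Brute-force P(case > control) + 0.5 P(tie) over all pairs."""
    cases = np.asarray(cases)[:, None]
    controls = np.asarray(controls)[None, :]
    return float(((cases > controls) + 0.5 * (cases == controls)).mean())


def delong_oracle(cases, controls):
    """Explicit V10/V01 structural-component enumeration."""
    m, n = len(cases), len(controls)
    psi = (np.asarray(cases)[:, None] > np.asarray(controls)[None, :]) \
        + 0.5 * (np.asarray(cases)[:, None] == np.asarray(controls)[None, :])
    auc = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


class TestRocFromCounts:
    def test_small_example(self):
        counts = np.array([2, 3, 1, 2])
        labels = np.array([1, 1, 0, 0])
        roc = roc_from_counts(counts, labels)
        assert roc.auc == pytest.approx(0.875)

    def test_endpoints_and_monotonicity(self, rng):
        counts = rng.integers(0, 10, size=200)
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]  # ensure both classes
        roc = roc_from_counts(counts, labels, n_symptoms=9)
        assert (roc.sensitivities[0], roc.specificities[0]) == (1.0, 0.0)
        assert (roc.sensitivities[-1], roc.specificities[-1]) == (0.0, 1.0)
        assert np.all(np.diff(roc.sensitivities) <= 0)
        assert np.all(np.diff(roc.specificities) >= 0)
        assert roc.thresholds[0] == -0.5 and roc.thresholds[-1] == 9.5

    def test_shuffled_labels_auc_near_half(self, rng):
        counts = rng.integers(0, 20, size=20_000)
        labels = rng.integers(0, 2, size=20_000)
        roc = roc_from_counts(counts, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_perfect_separation(self):
        counts = np.r_[np.full(50, 10), np.zeros(50, dtype=int)]
        labels = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        roc = roc_from_counts(counts, labels)
        assert roc.auc == 1.0
        i = np.argmax(np.abs(roc.sensitivities + roc.specificities - 1))
        assert roc.sensitivities[i] == 1.0 and roc.specificities[i] == 1.0
        assert roc.auc_ci == (1.0, 1.0)  # zero-variance interval

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_from_counts([1, 2, 3], [1, 1, 1])

    @settings(deadline=None)
    @given(cases=count_vectors, controls=count_vectors)
    def test_mann_whitney_equals_trapezoid(self, cases, controls):
        counts = np.array(cases + controls)
        labels = np.r_[np.ones(len(cases), int), np.zeros(len(controls), int)]
        roc = roc_from_counts(counts, labels)
        assert roc.auc == pytest.approx(pairwise_auc(cases, controls), abs=1e-12)
        assert roc.auc == pytest.approx(trapezoid_auc(roc), abs=1e-12)


class TestDeLong:
    @settings(deadline=None, max_examples=50)
    @given(cases=st.lists(st.integers(0, 8), min_size=2, max_size=10),
           controls=st.lists(st.integers(0, 8), min_size=2, max_size=10))
    def test_variance_matches_component_enumeration(self, cases, controls):
        counts = np.array(cases + controls)
        labels = np.r_[np.ones(len(cases), int), np.zeros(len(controls), int)]
        from symptomdx.roc import _delong_auc_variance

        auc, var = _delong_auc_variance(np.array(cases), np.array(controls))
        auc0, var0 = delong_oracle(cases, controls)
        assert auc == pytest.approx(auc0, abs=1e-10)
        assert var == pytest.approx(var0, abs=1e-10)
        lo, hi = delong_ci(counts, labels)
        assert 0.0 <= lo <= hi <= 1.0

    def test_symmetric_inputs_symmetric_interval(self):
        cases = [0, 1, 2, 3, 4]
        controls = [4, 3, 2, 1, 0]
        counts = np.array(cases + controls)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        lo, hi = delong_ci(counts, labels)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=1e-10)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            delong_ci([1, 0], [1, 0], level=1.5)


class TestBestOperatingPoint:
    def test_brute_force_agreement(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 12, size=100)
            labels = rng.integers(0, 2, size=100)
            labels[:2] = [0, 1]
            roc = roc_from_counts(counts, labels)
            bp = best_operating_point(roc)
            j = np.abs(roc.sensitivities + roc.specificities - 1)
            assert bp.youden_abs == pytest.approx(j.max())
            # ties broken toward the smallest threshold
            first = np.flatnonzero(j == j.max())[0]
            assert bp.threshold == roc.thresholds[first]

    def test_uninformative_roc_returns_smallest_threshold(self):
        # single shared count value: sens + spec = 1 at every cutpoint
        counts = np.full(40, 3)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        roc = roc_from_counts(counts, labels)
        bp = best_operating_point(roc)
        assert bp.youden_abs == pytest.approx(0.0)
        assert bp.threshold == -0.5


class TestAucCurve:
    def test_fig3_curve_increases_with_k(self, fig3_cohort):
        curve = auc_curve(fig3_cohort)
        assert curve.aucs[-1] > curve.aucs[0]
        assert curve.extremal_k >= 20   # maximum reached at large k
        assert curve.extremal_auc == curve.aucs.max()

    def test_k1_equals_binary_rule_auc(self, fig3_cohort, fig3_measures):
        curve = auc_curve(fig3_cohort)
        is_case = fig3_cohort.disease.astype(bool)
        s = fig3_cohort.symptoms[:, 0]
        sens = s[is_case].mean()
        spec = 1 - s[~is_case].mean()
        assert curve.aucs[0] == pytest.approx((sens + spec) / 2, abs=1e-12)
        n1 = is_case.sum()
        se = np.sqrt(0.2 * 0.8 / n1)
        assert curve.aucs[0] == pytest.approx(
            single_symptom_auc(fig3_measures), abs=4 * se)

    def test_rr_below_one_auc_below_half(self):
        m = EpidemiologicalMeasures(d=0.2, ir=0.4, rr=0.5, n_subjects=10_000,
                                    n_symptoms=40, seed=21)
        curve = auc_curve(simulate_cohort(m))
        assert curve.aucs[-1] < 0.5           # orientation never flipped
        assert curve.extremal_auc == curve.aucs.min()

    def test_rr_one_all_cis_overlap_extremal(self):
        m = EpidemiologicalMeasures(d=0.2, ir=0.2, rr=1.0, n_subjects=10_000,
                                    n_symptoms=40, seed=22)
        curve = auc_curve(simulate_cohort(m))
        assert curve.overlap_flags.all()

    def test_associated_target_uses_other_label(self, fig3_cohort):
        # rho_dd = 0: counts carry no information about the associated disease
        curve = auc_curve(fig3_cohort, target="associated")
        assert abs(curve.extremal_auc - 0.5) < 0.1
        with pytest.raises(ValueError):
            auc_curve(fig3_cohort, target="nonsense")

    def test_to_frame_schema(self, fig3_cohort):
        frame = auc_curve(fig3_cohort).to_frame()
        assert list(frame["k"]) == list(range(1, 41))
        assert {"auc", "ci_low", "ci_high", "threshold", "sensitivity",
                "specificity", "overlap", "target"} <= set(frame.columns)
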