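"""Patient-grouped splitting, consensus, metrics, repeated evaluation and
ROC analysis (including the pairwise-concordance AUC oracle)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serodisc import (CohortConfig, ModelSpec, PreprocessConfig, consensus,
                      make_axis, metrics, operating_points, pooled_roc,
                      roc_from_scores, run_repeats, simulate_cohort,
                      split_by_patient)
from serodisc.errors import DegenerateDataError, StratificationError
from serodisc.evaluate import PatientPrediction, ROCCurve

from conftest import make_patient_dataset


def auc_oracle(scores, labels):
    """Brute-force pairwise estimator P(s_case > s_ctrl) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    pos, neg = s[np.asarray(labels) == 1], s[np.asarray(labels) == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSplitByPatient:
    def test_cohort_a_arithmetic(self):
        ds = make_patient_dataset(100, 100, seed=1)
        plan = split_by_patient(ds, 0.7, seed=5)
        assert len(plan.train_patients) == 140
        assert len(plan.test_patients) == 60
        labels = ds.patient_labels()
        train_pos = sum(labels[p] for p in plan.train_patients)
        assert train_pos == 70  # stratified 70/30 within each class

    def test_same_seed_same_plan(self):
        ds = make_patient_dataset(5, 5, seed=2)
        a = split_by_patient(ds, seed=11)
        b = split_by_patient(ds, seed=11)
        assert a.train_patients == b.train_patients

    def test_partition_no_overlap(self):
        ds = make_patient_dataset(7, 9, seed=3)
        plan = split_by_patient(ds, seed=1)
        assert not set(plan.train_patients) & set(plan.test_patients)
        assert len(plan.train_patients) + len(plan.test_patients) == 16

    def test_single_patient_class_rejected(self):
        ds = make_patient_dataset(1, 5, seed=4)
        with pytest.raises(StratificationError):
            split_by_patient(ds, seed=0)


class TestConsensus:
    @pytest.mark.parametrize("votes,expected", [
        ([1, 1, 1, 1, 1, 0, 0, 0, 0], 1),
        ([1] * 9, 1),
        ([0] * 9, 0),
    ])
    def test_majority(self, votes, expected):
        assert consensus(votes) == expected

    @given(st.permutations([1, 1, 1, 1, 1, 0, 0, 0, 0]))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance(self, votes):
        assert consensus(votes) == 1

    def test_even_tie_needs_fallback(self):
        with pytest.raises(DegenerateDataError):
            consensus([1, 0])
        assert consensus([1, 0], mean_score=0.8) == 1
        assert consensus([1, 0], mean_score=0.2) == 0


class TestMetrics:
    def _preds(self, truths, labels):
        return [PatientPrediction(f"p{i}", t, [l] * 9, l, float(l))
                for i, (t, l) in enumerate(zip(truths, labels))]

    def test_all_correct(self):
        sens, spec, acc = metrics(self._preds([1, 1, 0, 0], [1, 1, 0, 0]))
        assert (sens, spec, acc) == (1, 1, 1)

    def test_all_wrong(self):
        sens, spec, acc = metrics(self._preds([1, 1, 0, 0], [0, 0, 1, 1]))
        assert (sens, spec, acc) == (0, 0, 0)

    def test_hand_confusion_matrix(self):
        truths = [1, 1, 1, 1, 0, 0, 0, 0]
        labels = [1, 1, 1, 0, 0, 0, 1, 1]  # TP=3 FN=1 TN=2 FP=2
        sens, spec, acc = metrics(self._preds(truths, labels))
        assert (sens, spec, acc) == (0.75, 0.5, 0.625)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DegenerateDataError):
            metrics(self._preds([1, 1], [1, 0]))


class _CentroidStub:
    """Family-agnostic model: score = projection onto the class-centroid
    difference direction; perfect on strongly separated data."""

    def build(self, X, y, seed):
        d = X[y == 1].mean(0) - X[y == 0].mean(0)
        mid = (X[y == 1].mean(0) + X[y == 0].mean(0)) / 2

        class M:
            threshold = 0.0
            feature_importances_ = None

            @staticmethod
            def score(Z):
                return (np.asarray(Z) - mid) @ d

        return M()


class _ConstantCancerStub:
    def build(self, X, y, seed):
        class M:
            threshold = 0.5
            feature_importances_ = None

            @staticmethod
            def score(Z):
                return np.ones(len(Z))

        return M()


@pytest.fixture(scope="module")
def separated_cohort():
    axis = make_axis(1800, 1000, 2)
    cfg = CohortConfig(n_cases=8, n_controls=8, effect_size=6.0,
                       marker_sd=0.0, patient_sd=0.002, bio_sd=0.001,
                       tech_sd=0.001, scatter_sd=0.05, baseline_sd=0.02,
                       seed=77)
    return simulate_cohort(cfg, axis)


class TestRunRepeats:
    def test_oracle_stub_scores_perfectly(self, separated_cohort):
        summary = run_repeats(separated_cohort, _CentroidStub(),
                              PreprocessConfig(), n_repeats=4, base_seed=2)
        assert summary.aggregate["sensitivity_mean"] == 1.0
        assert summary.aggregate["specificity_mean"] == 1.0
        assert summary.aggregate["accuracy_sd"] == 0.0

    def test_constant_cancer_stub(self, separated_cohort):
        summary = run_repeats(separated_cohort, _ConstantCancerStub(),
                              PreprocessConfig(), n_repeats=3, base_seed=2)
        assert summary.aggregate["sensitivity_mean"] == 1.0
        assert summary.aggregate["specificity_mean"] == 0.0

    def test_reproducible_from_base_seed(self, separated_cohort):
        kw = dict(n_repeats=3, base_seed=9)
        a = run_repeats(separated_cohort, ModelSpec("plsda",
                                                    grid={"n_latent": [3]}),
                        PreprocessConfig(), **kw)
        b = run_repeats(separated_cohort, ModelSpec("plsda",
                                                    grid={"n_latent": [3]}),
                        PreprocessConfig(), **kw)
        assert a.per_repeat.equals(b.per_repeat)


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_single_tie_hand_value(self):
        # one tied case/control pair among otherwise separated scores
        scores = [0.9, 0.5, 0.5, 0.1]
        labels = [1, 1, 0, 0]
        roc = roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(1 - 0.5 / 4, abs=1e-12)
        assert roc.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 50)
        labels = np.zeros(n, dtype=int)
        labels[:max(1, int(n) // 3)] = 1
        rng.shuffle(labels)
        # discretized scores force plenty of ties
        scores = np.round(rng.normal(size=n) + labels, 1)
        roc = roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(auc_oracle(scores, labels),
                                        abs=1e-12)

    def test_endpoints_present(self):
        roc = roc_from_scores([0.3, 0.7, 0.2, 0.9], [0, 1, 0, 1])
        assert (roc.sensitivity[0], roc.specificity[0]) == (0.0, 1.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1.0, 0.0)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert 0.45 < roc_from_scores(scores, labels).auc < 0.55


class TestOperatingPoints:
    def test_perfect_roc_all_points_at_corner(self):
        roc = roc_from_scores([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        pts = operating_points(roc, 0.6)
        assert pts.max_sensitivity == (1.0, 1.0)
        assert pts.max_specificity == (1.0, 1.0)
        assert pts.balanced == (1.0, 1.0)

    def test_diagonal_roc_boundary_convention(self):
        """A useless classifier's ROC only touches the constraint region on
        the sens == spec diagonal; boundary points are admitted."""
        thr = np.linspace(0, 1, 101)
        roc = ROCCurve(thr, sensitivity=1 - thr, specificity=thr, auc=0.5)
        pts = operating_points(roc, 0.45)
        assert not pts.empty
        s, p = pts.balanced
        assert s == pytest.approx(p, abs=0.02)
        assert s >= 0.45

    def test_region_nesting_45_vs_60(self):
        rng = np.random.default_rng(9)
        scores = np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
        labels = np.array([1] * 200 + [0] * 200)
        roc = roc_from_scores(scores, labels)
        a45 = operating_points(roc, 0.45).max_sensitivity
        a60 = operating_points(roc, 0.60).max_sensitivity
        assert a45[0] >= a60[0]

    def test_empty_region_reported(self):
        roc = roc_from_scores([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])  # inverted
        assert operating_points(roc, 0.9).empty


class TestLeakage:
    def test_spectra_follow_patients(self):
        ds = make_patient_dataset(6, 6, seed=8)
        # plant a unique marker value per patient in feature 0
        for i, pid in enumerate(ds.patients):
            ds.matrix[ds.rows_for_patients([pid]), 0] = 1000.0 + i
        plan = split_by_patient(ds, seed=3)
        train_rows = ds.rows_for_patients(plan.train_patients)
        test_rows = ds.rows_for_patients(plan.test_patients)
        train_markers = set(ds.matrix[train_rows, 0])
        test_markers = set(ds.matrix[test_rows, 0])
        assert not train_markers & test_markers

    def test_emsc_reference_ignores_test_rows(self, separated_cohort):
        from serodisc.preprocess import run_preprocess

        plan = split_by_patient(separated_cohort, seed=4)
        mask = np.zeros(separated_cohort.n_spectra, dtype=bool)
        mask[separated_cohort.rows_for_patients(plan.train_patients)] = True
        cfg = PreprocessConfig()
        out1 = run_preprocess(separated_cohort, cfg, train_mask=mask)
        tampered = separated_cohort.with_matrix(separated_cohort.matrix.copy())
        tampered.matrix[~mask] *= 5.0  # corrupt the test rows only
        out2 = run_preprocess(tampered, cfg, train_mask=mask)
        np.testing.assert_allclose(out1.matrix[mask], out2.matrix[mask],
                                   atol=1e-12)
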