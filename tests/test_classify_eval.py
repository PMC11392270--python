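import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehgpreterm.classify_eval import (
    BIOMARKER_OFFSET,
    BIOMARKER_WEIGHTS,
    ClassifierSpec,
    ROCCurve,
    _FastGNB,
    _FastLDA,
    average_boundary_2d,
    average_roc,
    average_threshold_1d,
    composite_biomarker,
    confusion_metrics,
    repeated_evaluation,
    roc_auc,
    train_classifier,
)
from ehgpreterm.errors import ParameterError
from ehgpreterm.resampling import LeakAudit, stratified_holdout

from conftest import make_table


class TestConfusionMetrics:
    def test_worked_counts(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        p = np.array([1, 1, 0, 0, 0, 0, 1])
        m = confusion_metrics(y, p)
        assert (m.TP, m.FN, m.TN, m.FP) == (2, 1, 3, 1)
        assert m.Se == pytest.approx(2 / 3)
        assert m.Sp == pytest.approx(3 / 4)
        assert m.PPV == pytest.approx(2 / 3)
        assert m.NPV == pytest.approx(3 / 4)
        assert m.CA == pytest.approx(5 / 7)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        m = confusion_metrics(y, y)
        assert (m.Se, m.Sp, m.PPV, m.NPV, m.CA) == (1, 1, 1, 1, 1)

    def test_all_term_predictor(self):
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning):
            m = confusion_metrics(y, np.zeros(4, dtype=int))
        assert m.Se == 0.0 and m.Sp == 1.0
        assert np.isnan(m.PPV)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics(np.array([]), np.array([]))

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold_exactly(self, pairs):
        y = np.array([a for a, _ in pairs])
        p = np.array([b for _, b in pairs])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = confusion_metrics(y, p)
        if m.TP + m.FN:
            assert m.Se == m.TP / (m.TP + m.FN)
        if m.TN + m.FP:
            assert m.Sp == m.TN / (m.TN + m.FP)
        assert m.CA == (m.TP + m.TN) / len(pairs)


def pair_count_auc(y, s):
    """Mann-Whitney AUC oracle: concordant pairs, ties half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9])).auc == 1.0

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        y[:2] = [0, 1]
        auc = roc_auc(y, rng.standard_normal(len(y))).auc
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting_oracle(self, rng):
        for i in range(50):
            r = np.random.default_rng(i)
            n = int(r.integers(4, 20))
            y = r.integers(0, 2, n)
            y[0], y[1] = 0, 1
            s = np.round(r.standard_normal(n), 1)  # induce ties
            assert roc_auc(y, s).auc == pytest.approx(pair_count_auc(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.standard_normal(102)[:102][: len(y)]
        a1 = roc_auc(y, s).auc
        a2 = roc_auc(y, np.exp(3 * s) + 5).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc(np.ones(5, dtype=int), np.arange(5.0))


class TestAverageROC:
    def test_single_curve_identity(self):
        c = ROCCurve(fpr=np.array([0, 0.5, 1.0]), tpr=np.array([0, 0.8, 1.0]), auc=0.65)
        avg = average_roc([c], n_grid=5)
        assert np.allclose(avg.mean_se, np.interp(avg.grid, c.fpr, c.tpr))
        assert np.all(avg.sd_se == 0)

    def test_two_step_curves_average_to_midpoint(self):
        c1 = ROCCurve(np.array([0, 0.2, 1.0]), np.array([0, 1.0, 1.0]), 0.9)
        c2 = ROCCurve(np.array([0, 0.8, 1.0]), np.array([0, 1.0, 1.0]), 0.6)
        avg = average_roc([c1, c2], n_grid=11)
        assert avg.mean_se[5] == pytest.approx(
            (np.interp(0.5, c1.fpr, c1.tpr) + np.interp(0.5, c2.fpr, c2.tpr)) / 2
        )

    def test_monotone_nondecreasing(self, rng):
        curves = []
        for i in range(5):
            r = np.random.default_rng(i)
            y = r.integers(0, 2, 40)
            y[0], y[1] = 0, 1
            curves.append(roc_auc(y, r.standard_normal(40)))
        avg = average_roc(curves)
        assert np.all(np.diff(avg.mean_se) >= -1e-12)


class TestClassifiers:
    def test_lda_separable_blobs(self):
        table = make_table(20, 20, n_features=2, seed=1, shift=8.0)
        model = train_classifier(ClassifierSpec("lda_pseudo"), table)
        assert np.array_equal(model.predict(table.values), table.y)

    def test_constant_column_trains_without_failure(self):
        table = make_table(10, 10, n_features=2, seed=2, shift=3.0)
        table.values["f1"] = 1.0
        model = train_classifier(ClassifierSpec("lda_pseudo"), table)
        assert set(model.predict(table.values)) <= {0, 1}

    def test_deterministic(self):
        table = make_table(15, 15, n_features=3, seed=3, shift=1.0)
        for kind in ("lda_pseudo", "qda_pseudo", "gnb_empirical", "svm_poly3", "svm_rbf"):
            m1 = train_classifier(ClassifierSpec(kind), table, seed=5)
            m2 = train_classifier(ClassifierSpec(kind), table, seed=5)
            assert np.array_equal(m1.predict(table.values), m2.predict(table.values))

    def test_likelihood_oriented_and_bounded(self):
        table = make_table(20, 20, n_features=1, seed=4, shift=5.0)
        for kind in ("lda_pseudo", "svm_rbf"):
            model = train_classifier(ClassifierSpec(kind), table)
            lik = model.likelihood(table.values)
            assert np.all((0 <= lik) & (lik <= 1))
            assert lik[table.y == 1].mean() > lik[table.y == 0].mean()

    @pytest.mark.parametrize("fast_cls,kind", [(_FastLDA, "lda_pseudo"), (_FastGNB, "gnb_empirical")])
    def test_fast_path_matches_sklearn(self, fast_cls, kind):
        # the closed-form inner-loop classifiers agree with the sklearn route
        for seed in range(20):
            table = make_table(12, 30, n_features=3, seed=seed, shift=0.8)
            X, y = table.values.to_numpy(), table.y
            fast = fast_cls().fit(X, y)
            ref = train_classifier(ClassifierSpec(kind), table)
            assert np.array_equal(fast.predict(X), ref.predict(table.values))


class TestRepeatedEvaluation:
    def _plans(self, table, n):
        return [
            stratified_holdout(table, seed=100 + i, repetition_index=i)
            for i in range(1, n + 1)
        ]

    def test_single_repetition_base_case(self):
        table = make_table(10, 40, n_features=1, seed=5, shift=4.0)
        summ = repeated_evaluation(
            table, ["f0"], ClassifierSpec("lda_pseudo"), self._plans(table, 1)
        )
        assert summ.n_reps == 1
        for m, (mean, sd) in summ.test_summary.items():
            assert sd == 0.0

    def test_planted_effect_generalizes(self):
        table = make_table(20, 80, n_features=1, seed=6, shift=3.0)
        summ = repeated_evaluation(
            table, ["f0"], ClassifierSpec("lda_pseudo"), self._plans(table, 10)
        )
        test_auc = summ.test_summary["AUC"][0]
        train_auc = summ.train_summary["AUC"][0]
        assert test_auc > 0.9
        assert abs(train_auc - test_auc) < 0.06

    def test_null_labels_near_chance(self):
        table = make_table(40, 40, n_features=1, seed=7)
        summ = repeated_evaluation(
            table, ["f0"], ClassifierSpec("lda_pseudo"), self._plans(table, 10)
        )
        assert summ.test_summary["CA"][0] == pytest.approx(0.5, abs=0.12)

    def test_audit_clean_on_proper_use(self):
        table = make_table(10, 40, n_features=2, seed=8, shift=1.0)
        audit = LeakAudit()
        repeated_evaluation(
            table, ["f0", "f1"], ClassifierSpec("gnb_empirical"),
            self._plans(table, 5), audit=audit,
        )
        assert audit.checked > 0 and audit.clean


class TestBoundaries:
    def test_threshold_inside_gap(self):
        table = make_table(20, 20, n_features=1, seed=9, shift=10.0)
        model = train_classifier(ClassifierSpec("lda_pseudo"), table)
        lo = float(table.values["f0"].min())
        hi = float(table.values["f0"].max())
        art = average_threshold_1d([model], lo, hi)
        prem_min = table.values["f0"][table.y == 1].min()
        term_max = table.values["f0"][table.y == 0].max()
        assert term_max < art.threshold < prem_min

    def test_average_of_two_thresholds(self):
        class Shim:
            def __init__(self, t):
                self.t = t
            def likelihood(self, X):
                X = np.asarray(X, dtype=float)
                return 1.0 / (1.0 + np.exp(-(X[:, 0] - self.t)))
        art = average_threshold_1d([Shim(2.0), Shim(4.0)], 0.0, 10.0)
        assert art.threshold == pytest.approx(3.0, abs=1e-6)

    def test_2d_lda_contour_matches_analytic_midline(self):
        # symmetric blobs along x: the LDA boundary is x = midpoint
        table = make_table(50, 50, n_features=2, seed=10)
        table.values.loc[table.labels == 1, "f0"] += 6.0
        model = train_classifier(ClassifierSpec("lda_pseudo"), table)
        art = average_boundary_2d(
            [model], x_range=(-4, 10), y_range=(-4, 4), n_grid=120
        )
        xs = np.concatenate([c[:, 0] for c in art.contours])
        assert xs.mean() == pytest.approx(3.0, abs=0.4)

    def test_single_model_identity(self):
        table = make_table(10, 10, n_features=2, seed=11, shift=2.0)
        model = train_classifier(ClassifierSpec("gnb_empirical"), table)
        art = average_boundary_2d([model], (-3, 3), (-3, 3), n_grid=20)
        XX, YY = np.meshgrid(art.grid_x, art.grid_y)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        assert np.allclose(art.likelihood.ravel(), model.likelihood(pts))


class TestCompositeBiomarker:
    def test_boundary_point_scores_near_zero(self):
        # pa = 0.66 lies on the boundary when mf solves the linear equation
        mf_star = (BIOMARKER_WEIGHTS[0] * 0.66 - BIOMARKER_OFFSET) / -BIOMARKER_WEIGHTS[1]
        score, _ = composite_biomarker(0.66, mf_star)
        assert score == pytest.approx(0.0, abs=1e-12)
        assert mf_star == pytest.approx(4.161, abs=5e-3)

    def test_premature_example(self):
        score, label = composite_biomarker(1.0, 3.5)
        assert score == pytest.approx(5.98 - 4.02 * 3.5 + 12.78, abs=1e-12)
        assert score == pytest.approx(4.69, abs=1e-12)
        assert label == 1

    def test_term_example(self):
        score, label = composite_biomarker(0.0, 5.0)
        assert score == pytest.approx(-7.32, abs=1e-12)
        assert label == -1

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            composite_biomarker(float("nan"), 4.0)
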