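"""PLS-DA fitting, prediction, cross-validation and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cppqsar import (
    ConfusionCounts,
    GeneratorConfig,
    confusion_metrics,
    descriptor_table,
    evaluate,
    fit,
    generate_corpus,
    predict,
    q2,
    split,
)
from cppqsar.plsda import SchemaError, _nipals_pls1


def separable_toy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([
        y * 4.0 + rng.normal(0, 0.2, n),  # perfectly separating signal
        rng.normal(0, 1, n),
    ])
    return X, y.astype(float)


class TestFit:
    def test_separating_column_splits_classes_around_threshold(self):
        X, y = separable_toy()
        model = fit(X, y, 1)
        scores, labels = predict(model, X)
        assert np.all(scores[y == 1] > 0.5)
        assert np.all(scores[y == 0] < 0.5)
        assert np.array_equal(labels, y)

    def test_one_component_matches_normal_equations_oracle(self):
        """1-component PLS == OLS of y on the first latent direction t."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1], float)
        model = fit(X, y, 1, autoscale=False)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = (Xc @ w).reshape(-1, 1)
        beta = np.linalg.solve(t.T @ t, t.T @ yc)  # normal equations on t
        expected = y.mean() + (t @ beta).ravel()
        assert model.decision_function(X) == pytest.approx(expected, abs=1e-8)

    def test_duplicated_column_predictions_unchanged(self):
        X, y = separable_toy()
        base = fit(X, y, 2)
        dup = fit(np.column_stack([X, X[:, 0]]), y, 2)
        assert dup.decision_function(np.column_stack([X, X[:, 0]])) == pytest.approx(
            base.decision_function(X), abs=1e-8
        )

    def test_matches_reference_pls_implementation(self):
        """Cross-check against scikit-learn's PLSRegression."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 8))
        y = (rng.standard_normal(40) > 0).astype(float)
        for k in (1, 3, 5):
            ours = fit(X, y, k).decision_function(X)
            ref = sklearn_pls.PLSRegression(n_components=k, scale=True)
            theirs = ref.fit(X, y).predict(X).ravel()
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_training_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 6))
        y = (rng.standard_normal(30) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        W, P, _ = _nipals_pls1(Xs, y - y.mean(), 4)
        T = Xs @ W @ np.linalg.inv(P.T @ W)
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_residual_norm_nonincreasing_in_components(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 6))
        y = (rng.standard_normal(25) > 0).astype(float)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        norms = []
        for k in range(1, 6):
            W, P, _ = _nipals_pls1(Xs, y - y.mean(), k)
            T = Xs @ W @ np.linalg.inv(P.T @ W)
            norms.append(np.linalg.norm(Xs - T @ P.T))
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_constant_column_warned_and_ignored(self):
        X, y = separable_toy()
        Xc = np.column_stack([X, np.full(len(y), 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            model = fit(Xc, y, 1, feature_names=["sig", "noise", "const"])
        assert model.coef[2] == 0.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            fit(X, np.ones(5), 1)


class TestPredict:
    def test_training_row_reproduces_training_score(self):
        X, y = separable_toy()
        model = fit(X, y, 2)
        all_scores, _ = predict(model, X)
        one_score, _ = predict(model, X[3:4])
        assert one_score[0] == pytest.approx(all_scores[3])

    def test_schema_mismatch_raises(self):
        X, y = separable_toy()
        model = fit(X, y, 1)
        with pytest.raises(SchemaError, match="expects 2"):
            predict(model, X[:, :1])

    def test_reference_cpps_classified_positive(self, scale, reference_peptides):
        """A model trained on strongly separated synthetic classes calls
        all four canonical CPPs positive."""
        corpus = generate_corpus(GeneratorConfig(n_per_class=300, seed=8))
        X = descriptor_table(list(corpus.peptides), scale).to_numpy()
        model = fit(X, np.array(corpus.labels), 3)
        Xref = descriptor_table(reference_peptides, scale).to_numpy()
        _, labels = predict(model, Xref)
        assert labels.tolist() == [1, 1, 1, 1]


class TestQ2:
    def test_predictable_response_approaches_one(self):
        X, y = separable_toy(n=60, seed=2)
        assert q2(X, y, 1, seed=0) > 0.95

    def test_permuted_labels_have_no_predictive_value(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 5))
        vals = [
            q2(X, rng.permutation(np.repeat([0.0, 1.0], 40)), 2, seed=s)
            for s in range(20)
        ]
        assert np.mean(vals) <= 0.05

    def test_q2_below_training_r2(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 6))
        y = (X[:, 0] + rng.normal(0, 1.0, 50) > 0).astype(float)
        model = fit(X, y, 2)
        resid = y - model.decision_function(X)
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert q2(X, y, 2, seed=0) <= r2

    def test_degenerate_folds_rejected(self):
        X, y = separable_toy(n=6)
        with pytest.raises(ValueError):
            q2(X, y, 1, folds=1)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert m == {"sensitivity": 100.0, "specificity": 100.0,
                     "accuracy": 100.0, "mcc": 100.0}

    def test_worked_example_against_direct_formulas(self):
        c = ConfusionCounts(tp=40, fn=10, tn=45, fp=5)
        m = confusion_metrics(c)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(90.0)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["mcc"] == pytest.approx(
            100 * 1750 / math.sqrt(45 * 50 * 50 * 55), abs=1e-9
        )
        assert m["mcc"] == pytest.approx(70.35, abs=0.01)

    def test_random_labels_center_mcc_at_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(1000):
            yt = rng.integers(0, 2, 200)
            yp = rng.integers(0, 2, 200)
            vals.append(confusion_metrics(ConfusionCounts.from_labels(yt, yp))["mcc"])
        assert abs(np.mean(vals)) < 1.0

    def test_all_zero_counts_flagged_undefined(self):
        m = confusion_metrics(ConfusionCounts(0, 0, 0, 0))
        assert all(math.isnan(v) for v in m.values())

    def test_mcc_symmetric_under_class_swap(self):
        a = confusion_metrics(ConfusionCounts(tp=30, tn=11, fp=7, fn=2))
        b = confusion_metrics(ConfusionCounts(tp=11, tn=30, fp=2, fn=7))
        assert a["mcc"] == pytest.approx(b["mcc"])
        assert a["sensitivity"] == pytest.approx(b["specificity"])

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 1000)] * 4))
    def test_metric_bounds(self, counts):
        m = confusion_metrics(ConfusionCounts(*counts))
        for key in ("sensitivity", "specificity", "accuracy"):
            assert math.isnan(m[key]) or 0 <= m[key] <= 100
        assert math.isnan(m["mcc"]) or -100 <= m["mcc"] <= 100

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestEvaluate:
    def test_overlap_with_training_rejected(self):
        X, y = separable_toy()
        model = fit(X, y, 1, training_sequences=("RKKW", "LLDE"))
        with pytest.raises(ValueError, match="overlaps"):
            evaluate(model, X, y, test_sequences=("RKKW",))

    def test_metrics_recomputable_from_serialized_counts(self):
        X, y = separable_toy(n=30, seed=9)
        model = fit(X[:20], y[:20], 1)
        report = evaluate(model, X[20:], y[20:])
        again = confusion_metrics(ConfusionCounts(**report["counts"]))
        assert report["metrics"] == again

    def test_model_json_roundtrip(self, tmp_path):
        from cppqsar import PLSDAModel

        X, y = separable_toy()
        model = fit(X, y, 2, training_sequences=("RK",))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSDAModel.from_json(path)
        assert back.decision_function(X) == pytest.approx(
            model.decision_function(X), abs=1e-12
        )
        assert back.training_sequences == model.training_sequences


class TestSyntheticRecovery:
    def test_strong_separation_preset_recovers_labels(self, scale):
        """Held-out sensitivity and specificity >= 90 (20-seed median)."""
        sens, spec = [], []
        for seed in range(20):
            corpus = generate_corpus(
                GeneratorConfig(n_per_class=150, separation="strong", seed=seed)
            )
            train, test = split(corpus, 0.5, seed=seed)
            Xtr = descriptor_table(list(train.peptides), scale).to_numpy()
            Xte = descriptor_table(list(test.peptides), scale).to_numpy()
            model = fit(Xtr, np.array(train.labels), 3,
                        training_sequences=train.sequences)
            m = evaluate(model, Xte, np.array(test.labels), test.sequences)["metrics"]
            sens.append(m["sensitivity"])
            spec.append(m["specificity"])
        assert np.median(sens) >= 90
        assert np.median(spec) >= 90
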