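"""Scaling, PLS-DA, VIP, Kennard–Stone, LOO-CV and ROC against independent oracles."""

import numpy as np
import pytest

from honeyscreen import chemometrics as cm
from honeyscreen.synthetic import SimulationDesign, simulate_feature_table


def two_class_data(n_per_class=10, n_features=20, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n_per_class, n_features))
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    X[:n_per_class, :3] -= effect / 2
    X[n_per_class:, :3] += effect / 2
    return X, y


class TestScale:
    def test_vast_formula_by_hand(self):
        # column with μ=10, s=2: x=12 → ((12−10)/2)·(10/2) = 5
        col = np.array([8.0, 10.0, 12.0])  # μ=10, s=2 (ddof=1)
        X = col[:, None]
        out = cm.scale(X, "vast")
        assert out.values[2, 0] == pytest.approx(5.0)

    @pytest.mark.parametrize("method", ["autoscale", "pareto", "vast"])
    def test_centering(self, method):
        X, _ = two_class_data()
        out = cm.scale(X, method)
        assert np.allclose(out.values.mean(axis=0), 0, atol=1e-12)

    def test_autoscale_unit_sd(self):
        X, _ = two_class_data()
        out = cm.scale(X, "autoscale")
        assert np.allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_vast_column_sd_is_mu_over_s(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(2, 0.5, (30, 5))
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        out = cm.scale(X, "vast")
        assert np.allclose(out.values.std(axis=0, ddof=1), mu / sd, rtol=1e-12)

    def test_zero_variance_column_dropped(self):
        X, _ = two_class_data()
        X[:, 5] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cm.scale(X, "autoscale")
        assert 5 in out.dropped
        assert out.values.shape[1] == X.shape[1] - 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cm.scale(np.ones((1, 3)), "vast")

    def test_apply_scaling_reproduces_training_transform(self):
        X, _ = two_class_data()
        out = cm.scale(X, "vast")
        assert np.allclose(cm.apply_scaling(out, X), out.values)


class TestPlsdaFit:
    def test_single_informative_feature_dominates_first_weight(self):
        rng = np.random.default_rng(0)
        n = 20
        y = np.array(["A"] * 10 + ["B"] * 10)
        X = rng.normal(0, 0.01, (n, 5))
        X[:, 2] = np.where(y == "A", -1.0, 1.0)  # perfectly correlated feature
        scaled = cm.scale(X, "autoscale")
        model = cm.plsda_fit(scaled.values, y, 1)
        assert np.argmax(np.abs(model.W[:, 0])) == 2
        pred, _ = cm.plsda_predict(model, scaled.values)
        assert np.all(pred == y)

    def test_constant_labels_rejected(self):
        X, _ = two_class_data()
        with pytest.raises(ValueError):
            cm.plsda_fit(X, np.array(["A"] * len(X)), 2)

    def test_too_many_components_rejected(self):
        X, y = two_class_data(n_per_class=3, n_features=4)
        with pytest.raises(ValueError):
            cm.plsda_fit(X, y, 10)

    def test_score_columns_orthogonal(self):
        X, y = two_class_data()
        model = cm.plsda_fit(cm.scale(X, "autoscale").values, y, 4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.allclose(off, 0, atol=1e-8)

    def test_ssy_components_sum_to_total(self):
        X, y = two_class_data()
        model = cm.plsda_fit(cm.scale(X, "vast").values, y, 3)
        assert model.ssy.sum() == pytest.approx(model.ssy_total)

    def test_full_rank_pls_equals_least_squares(self):
        # with C = rank(X), PLS fitted values reproduce the OLS fit of
        # the dummy-coded response on the feature space
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (12, 4))
        X -= X.mean(axis=0)
        y = np.array(["A", "B"] * 6)
        ycoded = np.where(y == "A", -1.0, 1.0)
        model = cm.plsda_fit(X, y, 4)
        _, fitted = cm.plsda_predict(model, X)
        beta, *_ = np.linalg.lstsq(X, ycoded - ycoded.mean(), rcond=None)
        ols_fitted = X @ beta + ycoded.mean()
        assert np.allclose(fitted, ols_fitted, atol=1e-8)

    def test_matches_sklearn_pls_predictions(self):
        # independent oracle: scikit-learn's NIPALS PLS regression
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_data(seed=5)
        scaled = cm.scale(X, "autoscale")
        ycoded = np.where(y == "A", -1.0, 1.0)
        for C in (1, 2, 3):
            model = cm.plsda_fit(scaled.values, y, C)
            _, ours = cm.plsda_predict(model, scaled.values)
            sk = PLSRegression(n_components=C, scale=False).fit(scaled.values, ycoded)
            theirs = sk.predict(scaled.values).ravel()
            assert np.allclose(ours, theirs, atol=1e-8), C

    def test_pure_noise_loo_near_chance(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, (30, 40))
        y = np.array(["A", "B"] * 15)
        err, _ = cm.loo_cv(X, y, 2, "autoscale")
        assert 0.25 <= err <= 0.75


class TestPredict:
    def test_training_consistency_on_separable_data(self):
        # positive intensities, as vast scaling presumes (μ/s factor)
        X, y = two_class_data(effect=4.0)
        X = X + 10.0
        scaled = cm.scale(X, "vast")
        model = cm.plsda_fit(scaled.values, y, 2)
        pred, _ = cm.plsda_predict(model, scaled.values)
        assert np.all(pred == y)

    def test_duplicated_row_identical_prediction(self):
        X, y = two_class_data()
        scaled = cm.scale(X, "autoscale")
        model = cm.plsda_fit(scaled.values, y, 2)
        _, s1 = cm.plsda_predict(model, scaled.values[3:4])
        _, s2 = cm.plsda_predict(model, scaled.values[3:4].copy())
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)

    def test_feature_mismatch_rejected(self):
        X, y = two_class_data()
        model = cm.plsda_fit(cm.scale(X, "autoscale").values, y, 2)
        with pytest.raises(ValueError, match="mismatch"):
            cm.plsda_predict(model, np.ones((2, 3)))


class TestVip:
    def test_two_equal_weights_give_unit_vip(self):
        # C=1 with symmetric features: both VIPs must equal 1
        X = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, -1.0]])
        y = np.array(["B", "A", "B", "A"])
        model = cm.plsda_fit(X, y, 1)
        assert np.allclose(cm.vip(model), 1.0)

    @pytest.mark.parametrize("C", [1, 2, 3])
    def test_mean_squared_vip_is_one(self, C):
        X, y = two_class_data(seed=C)
        model = cm.plsda_fit(cm.scale(X, "vast").values, y, C)
        assert np.mean(cm.vip(model) ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_injected_markers_rank_on_top(self):
        design = SimulationDesign(
            n_per_class=(20, 20), n_blanks=0, n_qc=0, seed=9
        )
        table, truth = simulate_feature_table(design)
        X = table.sample_matrix.to_numpy()
        y = table.sample_classes.to_numpy()
        model = cm.plsda_fit(cm.scale(X, "vast").values, y, 2)
        vips = cm.vip(model)
        order = np.argsort(-vips)
        top10 = set(table.sample_matrix.columns[order[:10]])
        assert top10 == set(truth.marker_ids)


def naive_kennard_stone(X, n):
    """Independent straight-loop re-implementation for small inputs."""
    X = np.asarray(X, dtype=float)
    m = len(X)
    d = [[float(np.linalg.norm(X[i] - X[j])) for j in range(m)] for i in range(m)]
    best, pair = -1.0, (0, 0)
    for i in range(m):
        for j in range(i + 1, m):
            if d[i][j] > best:
                best, pair = d[i][j], (i, j)
    sel = [pair[0]] if n == 1 else list(pair)
    while len(sel) < n:
        cand_best, cand = -1.0, None
        for i in range(m):
            if i in sel:
                continue
            mind = min(d[i][j] for j in sel)
            if mind > cand_best:
                cand_best, cand = mind, i
        sel.append(cand)
    return sorted(sel)


class TestKennardStone:
    def test_collinear_points_pick_extremes(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        plan = cm.kennard_stone(X, 2)
        assert list(plan.test) == [0, 3]

    def test_all_but_one(self):
        X = np.random.default_rng(0).normal(0, 1, (6, 2))
        plan = cm.kennard_stone(X, 5)
        assert len(plan.test) == 5 and len(plan.train) == 1

    def test_duplicated_points_deterministic(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        a = cm.kennard_stone(X, 2)
        b = cm.kennard_stone(X, 2)
        assert list(a.test) == list(b.test)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (8, 3))
        for n in (1, 2, 4, 7):
            plan = cm.kennard_stone(X, n)
            assert list(plan.test) == naive_kennard_stone(X, n), (seed, n)

    def test_invalid_sizes_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            cm.kennard_stone(X, 0)
        with pytest.raises(ValueError):
            cm.kennard_stone(X, 4)


class TestLooCv:
    def test_separable_data_zero_error(self):
        X, y = two_class_data(effect=5.0)
        err, assignments = cm.loo_cv(X, y, 2, "autoscale")
        assert err == 0.0
        assert assignments == list(y)

    def test_permuted_labels_near_chance(self):
        design = SimulationDesign(n_per_class=(15, 15), n_blanks=0, n_qc=0, seed=2)
        table, _ = simulate_feature_table(design)
        X = table.sample_matrix.to_numpy()
        rng = np.random.default_rng(17)
        y_perm = rng.permutation(table.sample_classes.to_numpy())
        err, _ = cm.loo_cv(X, y_perm, 2, "vast")
        assert 0.35 <= err <= 0.65

    def test_minimal_n3_runs(self):
        X = np.array([[0.0, 0.1], [0.1, 0.0], [5.0, 5.0]])
        y = np.array(["A", "A", "B"])
        with pytest.warns(UserWarning, match="single member"):
            err, assignments = cm.loo_cv(X, y, 1, "autoscale")
        assert err == 0.0
        assert assignments[2] is None  # the singleton-class fold is skipped

    def test_singleton_class_fold_skipped_with_warning(self):
        X = np.vstack([np.zeros((1, 3)), np.ones((5, 3)) + np.arange(5)[:, None] * 0.1])
        y = np.array(["A", "B", "B", "B", "B", "B"])
        with pytest.warns(UserWarning, match="single member"):
            err, assignments = cm.loo_cv(X, y, 1, "autoscale")
        assert assignments.count(None) == 1


class TestRoc:
    def test_perfectly_ordered_scores(self):
        scores = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        out = cm.roc(scores, labels)
        assert out.auc == pytest.approx(1.0)

    def test_identical_scores_chance(self):
        out = cm.roc(np.zeros(10), np.array(["A", "B"] * 5))
        assert out.auc == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 30)
        labels = np.where(rng.random(30) < 0.5, "A", "B")
        if len(set(labels)) < 2:
            labels[0] = "A" if labels[0] == "B" else "B"
        a = cm.roc(scores, labels).auc
        b = cm.roc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 40)
        labels = np.array(["A"] * 20 + ["B"] * 20)
        scores[20:] += 1.0
        ours = cm.roc(scores, labels).auc
        theirs = roc_auc_score((labels == "B").astype(int), scores)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 50)
        labels = np.array(["A", "B"] * 25)
        out = cm.roc(scores, labels)
        fpr = 1 - out.specificity
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(out.sensitivity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cm.roc(np.arange(4.0), np.array(["A"] * 4))


class TestModelSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = two_class_data(seed=6)
        scaled = cm.scale(X, "vast")
        model = cm.plsda_fit(scaled.values, y, 2)
        path = tmp_path / "model.json"
        cm.save_model(model, str(path))
        reloaded = cm.load_model(str(path))
        pred_a, score_a = cm.plsda_predict(model, scaled.values)
        pred_b, score_b = cm.plsda_predict(reloaded, scaled.values)
        assert np.array_equal(pred_a, pred_b)
        assert np.allclose(score_a, score_b)
        assert np.allclose(cm.vip(model), cm.vip(reloaded))
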