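"""OPLS-DA fitting, prediction, VIP and oracle equivalence with PLS1."""

import numpy as np
import pandas as pd
import pytest

from csfomics.errors import DegenerateLabelError, RankError, SchemaError
from csfomics.oplsda import TrainedModel, fit_oplsda, predict, transform, vip


def nipals_pls1_predict(Xtr, ytr, Xte):
    """Independent single-component NIPALS PLS1 oracle.

    Unit-variance scaling (ddof=1), y centered; iterative NIPALS loop
    kept deliberately naive and separate from the package implementation.
    """
    Xtr = np.asarray(Xtr, float)
    Xte = np.asarray(Xte, float)
    y = np.asarray(ytr, float)
    mu, sd = Xtr.mean(0), Xtr.std(0, ddof=1)
    E = (Xtr - mu) / sd
    f = y - y.mean()
    u = f.copy()
    w = np.zeros(E.shape[1])
    for _ in range(500):
        w_new = E.T @ u / (u @ u)
        w_new /= np.linalg.norm(w_new)
        t = E @ w_new
        u = f * (f @ t) / (f @ f)  # single y: q scalar
        if np.linalg.norm(w_new - w) < 1e-14:
            w = w_new
            break
        w = w_new
    t = E @ w
    b = (t @ f) / (t @ t)
    t_new = ((Xte - mu) / sd) @ w
    return b * t_new + y.mean()


class TestFit:
    def test_separable_clouds_high_r2_and_training_accuracy(self, separable_clouds):
        X, y = separable_clouds
        m = fit_oplsda(X, y, n_orth=0)
        _, calls = predict(m, X)
        assert (calls == y).mean() == 1.0
        assert m.r2y > 0.9

    def test_north_zero_matches_nipals_pls_oracle(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, n_orth=0, compute_q2=False)
        scores, _ = predict(m, X)
        expected = nipals_pls1_predict(X, 2.0 * y - 1.0, X)
        assert np.allclose(scores, expected, atol=1e-8)

    def test_north_zero_matches_sklearn_pls(self, planted_matrix):
        from sklearn.cross_decomposition import PLSRegression

        X, y = planted_matrix
        m = fit_oplsda(X, y, n_orth=0, compute_q2=False)
        scores, _ = predict(m, X)
        sk = PLSRegression(n_components=1, scale=True).fit(X, 2.0 * y - 1.0)
        assert np.allclose(scores, sk.predict(X).ravel(), atol=1e-8)

    def test_orthogonal_noise_feature_leaves_scores_unchanged(self, planted_matrix):
        X, y = planted_matrix
        rng = np.random.default_rng(9)
        yc = (2.0 * y - 1.0) - (2.0 * y - 1.0).mean()
        z = rng.normal(size=len(y))
        # orthogonalize z against the outcome and every existing column
        basis = np.c_[yc, X.to_numpy() - X.to_numpy().mean(0)]
        q, _ = np.linalg.qr(basis)
        z = z - q @ (q.T @ z)
        z = (z - z.mean()) / z.std(ddof=1)
        X2 = X.copy()
        X2["z"] = z
        m1 = fit_oplsda(X, y, n_orth=1, compute_q2=False)
        m2 = fit_oplsda(X2, y, n_orth=1, compute_q2=False)
        assert np.allclose(m1.t, m2.t, atol=1e-6)

    def test_single_class_rejected(self, planted_matrix):
        X, _ = planted_matrix
        with pytest.raises(DegenerateLabelError):
            fit_oplsda(X, np.ones(len(X), dtype=int))

    def test_rank_error_when_too_many_orthogonal_components(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        y = np.array([1] * 5 + [0] * 5)
        with pytest.raises(RankError):
            fit_oplsda(X, y, n_orth=5, compute_q2=False)

    def test_constant_feature_dropped_with_uv_scaling(self, planted_matrix):
        X, y = planted_matrix
        X = X.copy()
        X["const"] = 3.0
        m = fit_oplsda(X, y, compute_q2=False)
        assert "const" in m.dropped_features
        assert "const" not in m.feature_ids

    def test_orthogonality_invariants(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, n_orth=2, compute_q2=False)
        assert np.linalg.norm(m.w) == pytest.approx(1.0)
        for k in range(2):
            assert abs(m.t_orth[k] @ m.t) < 1e-8 * max(1, np.linalg.norm(m.t))
        assert abs(m.t_orth[0] @ m.t_orth[1]) < 1e-6
        assert 0.0 <= m.r2y <= 1.0


class TestPredict:
    def test_training_matrix_reproduces_stored_scores(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, n_orth=1, compute_q2=False)
        t, _ = transform(m, X)
        assert np.allclose(t, m.t, atol=1e-10)

    def test_duplicated_sample_identical_score(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, compute_q2=False)
        row = X.iloc[[3]]
        s1, _ = predict(m, row)
        s2, _ = predict(m, pd.concat([row, row]))
        assert s2[0] == s2[1]
        assert s2[0] == pytest.approx(s1[0], rel=1e-12)

    def test_heldout_separable_accuracy_one(self, separable_clouds):
        X, y = separable_clouds
        m = fit_oplsda(X.iloc[5:-5], y[5:-5], n_orth=0, compute_q2=False)
        _, calls = predict(m, pd.concat([X.iloc[:5], X.iloc[-5:]]))
        assert (calls == np.r_[y[:5], y[-5:]]).all()

    def test_feature_order_permutation_invariance(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, compute_q2=False)
        shuffled = X[list(X.columns[::-1])]
        s1, _ = predict(m, X)
        s2, _ = predict(m, shuffled)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_affine_feature_rescaling_invariance_under_uv(self, planted_matrix):
        X, y = planted_matrix
        X2 = X.copy()
        X2["f00"] = X2["f00"] * 17.0 - 4.0
        m1 = fit_oplsda(X, y, compute_q2=False)
        m2 = fit_oplsda(X2, y, compute_q2=False)
        s1, _ = predict(m1, X)
        s2, _ = predict(m2, X2)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_feature_mismatch_rejected(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, compute_q2=False)
        with pytest.raises(SchemaError):
            predict(m, X[X.columns[:-1]])


class TestVip:
    def test_planted_feature_has_max_vip(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(60, 12)),
                         columns=[f"v{i}" for i in range(12)])
        y = np.array([1] * 30 + [0] * 30)
        X.iloc[:30, 0] += 3.0
        m = fit_oplsda(X, y, compute_q2=False)
        table = vip(m)
        assert table["vip"].idxmax() == "v0"

    def test_identical_copies_equal_vip(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=40) + np.r_[np.ones(20), np.zeros(20)]
        X = pd.DataFrame({f"c{i}": base for i in range(4)})
        y = np.array([1] * 20 + [0] * 20)
        m = fit_oplsda(X, y, n_orth=0, compute_q2=False)
        v = vip(m)["vip"].to_numpy()
        assert np.allclose(v, v[0])

    def test_mean_square_normalization(self, planted_matrix):
        X, y = planted_matrix
        m = fit_oplsda(X, y, compute_q2=False)
        v = vip(m)["vip"].to_numpy()
        assert np.mean(v**2) == pytest.approx(1.0, abs=1e-6)
        assert (v >= 0).all()


class TestModelQuality:
    def test_q2_not_above_r2_on_average(self):
        rng = np.random.default_rng(12)
        diffs = []
        for s in range(50):
            X = pd.DataFrame(rng.normal(size=(40, 8)))
            y = np.array([1] * 20 + [0] * 20)
            X.iloc[:20, 0] += 1.0
            m = fit_oplsda(X, y, seed=s)
            diffs.append(m.r2y - m.q2)
        assert np.mean(diffs) > 0

    def test_permuted_labels_q2_centers_at_or_below_zero(self):
        rng = np.random.default_rng(13)
        q2s, r2s = [], []
        for s in range(40):
            X = pd.DataFrame(rng.normal(size=(40, 8)))
            y = rng.permutation([1] * 20 + [0] * 20)
            m = fit_oplsda(X, y, seed=s)
            q2s.append(m.q2)
            r2s.append(m.r2y)
        assert np.mean(q2s) <= 0.0
        assert np.mean(r2s) > np.mean(q2s)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, planted_matrix, tmp_path):
        X, y = planted_matrix
        m = fit_oplsda(X, y, n_orth=1, compute_q2=False)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = TrainedModel.from_json(path)
        s1, c1 = predict(m, X)
        s2, c2 = predict(m2, X)
        assert np.allclose(s1, s2)
        assert (c1 == c2).all()
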