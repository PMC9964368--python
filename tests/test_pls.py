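"""PLS1/NIPALS correctness against independent oracles.

Oracle 1: a separately coded NIPALS recursion (kept deliberately
naive).  Oracle 2: ordinary least squares, which PLS must reproduce at
full rank.  Oracle 3: scikit-learn's PLSRegression for an external
cross-check of predictions.
"""

import numpy as np
import pytest

from mealnir.pls import (
    CVResult,
    PLSError,
    cross_validate,
    cv_folds,
    fit_pls1,
    predict,
    select_n_lv,
)


def nipals_oracle(X, y, n_lv):
    """Independent NIPALS recursion (power-iteration style, no reuse)."""
    X = X - X.mean(axis=0)
    y = y - y.mean()
    W, P, Q, T = [], [], [], []
    for _ in range(n_lv):
        w = X.T @ y
        w = w / np.sqrt(w @ w)
        t = X @ w
        p = X.T @ t / (t @ t)
        q = (y @ t) / (t @ t)
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w); P.append(p); Q.append(q); T.append(t)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    b = W @ np.linalg.inv(P.T @ W) @ Q
    return W, P, Q, np.array(T).T, b


@pytest.fixture
def noisy_instance(rng):
    n, p = 30, 8
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.1 * rng.standard_normal(n)
    return X, y


class TestFitPLS1:
    def test_single_component_exact_fit(self, rng):
        X = rng.standard_normal((20, 5))
        y = 3.0 * X[:, 2]
        model = fit_pls1(X, y, n_lv=1)
        # y proportional to one centred column need not be rank-one in X,
        # but one LV suffices when X's other columns are orthogonal to y;
        # construct that case explicitly
        Xo = np.zeros((20, 5))
        Xo[:, 2] = rng.standard_normal(20)
        yo = 3.0 * Xo[:, 2]
        m = fit_pls1(Xo, yo, n_lv=1)
        resid = yo - predict(m, Xo)
        assert np.sqrt(np.mean(resid**2)) <= 1e-10

    def test_full_rank_equals_ols(self, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=X.shape[1])
        Xc = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), Xc @ beta, atol=1e-8)

    def test_ols_equivalence_many_seeds(self):
        # 50 random small instances: PLS at n_lv = rank(X) is OLS
        for seed in range(50):
            r = np.random.default_rng(seed)
            n, p = r.integers(8, 20), r.integers(2, 6)
            X = r.standard_normal((int(n), int(p)))
            y = r.standard_normal(int(n))
            model = fit_pls1(X, y, n_lv=int(p))
            Xc = np.column_stack([np.ones(int(n)), X])
            beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
            np.testing.assert_allclose(predict(model, X), Xc @ beta, atol=1e-8)

    def test_matches_independent_nipals_oracle(self):
        X = np.array(
            [
                [1.0, 2.0, 0.0, 4.0],
                [3.0, 1.0, 2.0, 0.0],
                [0.0, 4.0, 1.0, 2.0],
                [2.0, 0.0, 3.0, 1.0],
                [4.0, 2.0, 1.0, 3.0],
                [1.0, 3.0, 4.0, 0.0],
            ]
        )
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        model = fit_pls1(X, y, n_lv=2)
        W, P, Q, T, b = nipals_oracle(X, y, 2)
        np.testing.assert_allclose(model.weights, W, atol=1e-10)
        np.testing.assert_allclose(model.x_loadings, P, atol=1e-10)
        np.testing.assert_allclose(model.y_loadings, Q, atol=1e-10)
        np.testing.assert_allclose(model.scores, T, atol=1e-10)
        np.testing.assert_allclose(model.coef, b, atol=1e-10)

    def test_scores_orthogonal(self, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=5)
        T = model.scores
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_residual_norm_non_increasing(self, noisy_instance):
        X, y = noisy_instance
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        Xd, yd = Xc.copy(), yc.copy()
        norms = [np.linalg.norm(Xd)]
        model = fit_pls1(X, y, n_lv=5)
        for k in range(5):
            t = model.scores[:, k]
            Xd = Xd - np.outer(t, model.x_loadings[:, k])
            norms.append(np.linalg.norm(Xd))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_permutation_invariance(self, rng, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3)
        perm = rng.permutation(len(y))
        model_p = fit_pls1(X[perm], y[perm], n_lv=3)
        grid = rng.standard_normal((4, X.shape[1]))
        np.testing.assert_allclose(
            predict(model, grid), predict(model_p, grid), atol=1e-10
        )

    def test_matches_sklearn_cross_check(self, noisy_instance):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3)
        ours = predict(model, X)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        theirs = ref.predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_errors(self, noisy_instance):
        X, y = noisy_instance
        with pytest.raises(PLSError):
            fit_pls1(X, y, n_lv=X.shape[1] + 1)
        with pytest.raises(PLSError):
            fit_pls1(X, np.ones_like(y), n_lv=1)  # zero-variance target


class TestPredict:
    def test_training_predictions_reproduced(self, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3)
        fitted = model.y_mean + model.scores @ model.y_loadings
        np.testing.assert_allclose(predict(model, X), fitted, atol=1e-10)

    def test_row_of_means_predicts_mean_y(self, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3)
        assert predict(model, X.mean(axis=0)[None, :])[0] == pytest.approx(
            np.mean(y), abs=1e-10
        )

    def test_matches_matrix_product_oracle(self, rng, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3)
        Xnew = rng.standard_normal((7, X.shape[1]))
        expected = model.y_mean + (Xnew - model.x_mean) @ model.coef
        np.testing.assert_allclose(predict(model, Xnew), expected, atol=1e-12)

    def test_wavelength_mismatch(self, noisy_instance):
        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=2)
        with pytest.raises(PLSError):
            predict(model, np.zeros((2, X.shape[1] + 1)))

    def test_json_round_trip(self, noisy_instance, tmp_path):
        from mealnir.pls import PLSModel

        X, y = noisy_instance
        model = fit_pls1(X, y, n_lv=3, metadata={"analyte": "fat"})
        back = PLSModel.from_json(model.to_json())
        np.testing.assert_allclose(predict(back, X), predict(model, X),
                                   atol=1e-12)
        assert back.metadata["analyte"] == "fat"


class TestCrossValidate:
    def test_perfect_linear_data_selects_one_lv(self, rng):
        X = rng.standard_normal((24, 6))
        # rank-one signal: y along a single latent direction, no noise
        w = rng.standard_normal(6)
        y = X @ w
        X = np.outer(X @ w, w) / (w @ w)  # make X itself rank one
        cv = cross_validate(X, y, max_lv=3, scheme="venetian", n_splits=6)
        assert cv.chosen_n_lv == 1
        assert cv.rmsecv[0] <= 1e-8

    def test_venetian_fold_assembly(self):
        folds = cv_folds(10, "venetian", 5)
        expected = [[0, 5], [1, 6], [2, 7], [3, 8], [4, 9]]
        assert [f.tolist() for f in folds] == expected

    def test_matches_naive_refit_loop(self, noisy_instance):
        X, y = noisy_instance
        max_lv = 4
        cv = cross_validate(X, y, max_lv=max_lv, scheme="venetian", n_splits=5)
        n = len(y)
        press = np.zeros(max_lv)
        for held in cv_folds(n, "venetian", 5):
            keep = np.setdiff1d(np.arange(n), held)
            for k in range(1, max_lv + 1):
                m = fit_pls1(X[keep], y[keep], k)  # full refit per LV
                pred = predict(m, X[held])
                press[k - 1] += np.sum((y[held] - pred) ** 2)
        np.testing.assert_allclose(cv.rmsecv, np.sqrt(press / n), atol=1e-9)

    def test_loo_and_blocks_schemes(self, noisy_instance):
        X, y = noisy_instance
        assert len(cv_folds(10, "loo")) == 10
        blocks = cv_folds(10, "blocks", 3)
        assert sorted(np.concatenate(blocks).tolist()) == list(range(10))
        cv = cross_validate(X, y, max_lv=3, scheme="loo")
        assert cv.rmsecv.shape == (3,)


class TestSelectNLV:
    @pytest.mark.parametrize(
        "rmsecv, cap, expected",
        [
            ([5, 2, 1, 1.5], 10, 3),   # unique minimum
            ([3, 1, 1, 2], 10, 2),     # tie goes to the smaller model
            (list(np.linspace(15, 1, 15)), 10, 10),  # cap binds
        ],
    )
    def test_selection_rule(self, rmsecv, cap, expected):
        cv = CVResult(rmsecv=np.array(rmsecv, dtype=float), scheme="t",
                      chosen_n_lv=1)
        assert select_n_lv(cv, cap=cap) == expected
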