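"""Regression methods, cross-validation and sample selection.

Each method is checked against an independent oracle: exhaustive best-subset
search for the stepwise regression, scikit-learn's PLS for the SIMPLS core,
an explicitly assembled dense linear system for the LS-SVM, and a
brute-force re-implementation for Kennard-Stone.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from protir.chemometrics import (
    ZETA_CAP,
    PredictorBlock,
    aslr_fit,
    evaluate_all,
    kennard_stone_select,
    loo_cv,
    lssvm_fit,
    lssvm_tune,
    median_heuristic,
    pls_fit,
    pls_select_lv,
    rbf_kernel,
    _lssvm_loo_rmse,
    _pls_loo_rmse_curve,
)
from protir.spectral_model import ParameterError
from protir.synthetic import GeneratorConfig, sample_compositions, sample_structures


# --------------------------------------------------------------- oracles
def _oracle_loo_rmse(X, y, cols):
    """LOO RMSE of OLS on feature subset, by explicit refits (no hat matrix)."""
    n = len(y)
    errs = []
    for i in range(n):
        tr = np.arange(n) != i
        Z = np.column_stack([np.ones(tr.sum()), X[tr][:, cols]])
        beta, *_ = np.linalg.lstsq(Z, y[tr], rcond=None)
        pred = beta[0] + X[i, cols] @ beta[1:]
        errs.append((pred - y[i]) ** 2)
    return np.sqrt(np.mean(errs))


def _oracle_kennard_stone(T, k):
    """Straightforward KS with explicit loops."""
    T = np.asarray(T, float)
    sd = T.std(axis=0)
    sd[sd == 0] = 1.0
    T = (T - T.mean(axis=0)) / sd
    n = len(T)
    D = np.array([[np.sum((T[i] - T[j]) ** 2) for j in range(n)] for i in range(n)])
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best:
                best, pair = D[i, j], (i, j)
    sel = list(pair)
    while len(sel) < k:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in sel:
                continue
            d = min(D[i][j] for j in sel)
            if d > cand_best:
                cand_best, cand = d, i
        sel.append(cand)
    return sel


class TestAslr:
    def test_exact_single_feature_dependence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        labels = [1600.0 + 8 * j for j in range(10)]
        y = 2.0 * X[:, 7]  # feature labelled 1656
        m = aslr_fit(PredictorBlock(X, labels), y, max_terms=3)
        assert m.features[0] == 1656.0
        assert m.coef[0] == pytest.approx(2.0, abs=1e-9)
        assert np.abs(m.predict(X) - y).max() < 1e-9

    def test_max_terms_one_equals_exhaustive_single_scan(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=25)
        m = aslr_fit(PredictorBlock(X, list(range(8))), y, max_terms=1)
        best = min(range(8), key=lambda j: _oracle_loo_rmse(X, y, [j]))
        assert m.feature_idx == [best]

    def test_two_term_model_matches_best_subset_when_greedy_is_optimal(self):
        # near-orthogonal features: greedy forward selection is optimal
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = 1.5 * X[:, 1] - 2.0 * X[:, 3] + 0.1 * rng.normal(size=30)
        m = aslr_fit(PredictorBlock(X, list(range(5))), y, max_terms=2)
        pairs = {p: _oracle_loo_rmse(X, y, list(p))
                 for p in itertools.combinations(range(5), 2)}
        best_pair = min(pairs, key=pairs.get)
        assert set(m.feature_idx) == set(best_pair)
        assert m.criterion_path[-1] == pytest.approx(pairs[best_pair], rel=1e-9)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ParameterError):
            aslr_fit(PredictorBlock(X, list(range(4))), np.full(20, 5.0))

    def test_recovers_planted_composition_model(self):
        # helix content planted as a 5-residue linear model on compositions
        plant = {"L": 3.3, "P": -4.8, "T": -1.9, "V": -2.3, "A": 1.3}
        aa = "ACDEFGHIKLMNPQRSTVWY"
        hits = 0
        for rep in range(5):
            cfg = GeneratorConfig(n_proteins=92, seed=500 + rep)
            comps = sample_compositions(sample_structures(cfg), cfg)
            X = np.array([[c.percent(a) for a in aa] for c in comps])
            rng = np.random.default_rng(600 + rep)
            y = 39.1 + sum(co * X[:, aa.index(r)] for r, co in plant.items())
            y = y + rng.normal(0.0, 5.0, len(y))
            m = aslr_fit(PredictorBlock(X, list(aa)), y, max_terms=5)
            hits += set(m.features) == set(plant)
        assert hits >= 4


class TestPls:
    def test_rank_one_block_needs_one_lv(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=20)
        v = rng.normal(size=12)
        X = np.outer(u, v)
        y = 3.0 * u + 1.0
        m = pls_fit(X, y, 1)
        assert np.abs(m.predict(X) - y).max() < 1e-9

    def test_full_rank_pls_equals_ols_on_training_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = pls_fit(X, y, 6)
        Z = np.column_stack([np.ones(25), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(m.predict(X), Z @ beta, atol=1e-8)

    @pytest.mark.parametrize("lv", [1, 2, 5])
    def test_predictions_match_sklearn(self, lv):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 15))
        y = X @ rng.normal(size=15) + rng.normal(size=30)
        Xt = rng.normal(size=(8, 15))
        mine = pls_fit(X, y, lv).predict(Xt)
        sk = PLSRegression(n_components=lv, scale=False).fit(X, y).predict(Xt).ravel()
        np.testing.assert_allclose(mine, sk, atol=1e-10)

    def test_lv_selection_follows_first_minimum_rule(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 20))
        y = X[:, :3] @ np.array([2.0, -1.0, 0.5]) + 0.3 * rng.normal(size=40)
        curve = _pls_loo_rmse_curve(X, y, 10)
        chosen = pls_select_lv(X, y, max_lv=10)
        best = curve.min()
        assert curve[chosen - 1] <= 1.02 * best
        assert all(curve[a] > 1.02 * best for a in range(chosen - 1))

    def test_excessive_lv_request_clipped_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="clipped"):
            m = pls_fit(X, y, 9)
        assert m.n_lv <= 4


class TestLssvm:
    def test_constant_response_predicted_everywhere(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 3))
        m = lssvm_fit(X, np.full(15, 4.2), gamma=10.0)
        np.testing.assert_allclose(m.predict(rng.normal(size=(5, 3))), 4.2, atol=1e-8)
        assert np.abs(m.alpha).max() < 1e-8

    def test_interpolates_training_points_as_gamma_grows(self):
        rng = np.random.default_rng(9)
        X = np.linspace(0.0, 9.0, 10)[:, None]  # well-separated points
        y = rng.normal(size=10)
        m = lssvm_fit(X, y, gamma=1e9, bandwidth=1.0)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-5)

    def test_matches_independent_dense_solve(self):
        # 6-point 1-D toy, fixed gamma and bandwidth
        X = np.array([[0.0], [0.5], [1.1], [1.9], [2.6], [3.4]])
        y = np.array([0.1, 0.4, 0.9, 0.7, 0.2, -0.3])
        g, bw = 10.0, 1.0
        m = lssvm_fit(X, y, gamma=g, bandwidth=bw)
        # oracle: assemble and solve the saddle system from scratch
        K = np.exp(-((X - X.T) ** 2) / (2 * bw**2))
        n = len(y)
        M = np.block([[np.zeros((1, 1)), np.ones((1, n))],
                      [np.ones((n, 1)), K + np.eye(n) / g]])
        sol = np.linalg.lstsq(M, np.concatenate([[0.0], y]), rcond=None)[0]
        assert m.b == pytest.approx(sol[0], abs=1e-9)
        np.testing.assert_allclose(m.alpha, sol[1:], atol=1e-9)
        xq = np.array([[0.7], [2.0]])
        oracle_pred = np.exp(-((xq - X.T) ** 2) / (2 * bw**2)) @ sol[1:] + sol[0]
        np.testing.assert_allclose(m.predict(xq), oracle_pred, atol=1e-9)

    def test_closed_form_loo_equals_explicit_refits(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        bw, g = 1.3, 10.0
        fast = _lssvm_loo_rmse(rbf_kernel(X, X, bw), y, g)
        errs = []
        for i in range(12):
            tr = np.arange(12) != i
            m = lssvm_fit(X[tr], y[tr], gamma=g, bandwidth=bw)
            errs.append((m.predict(X[i:i + 1])[0] - y[i]) ** 2)
        assert fast == pytest.approx(np.sqrt(np.mean(errs)), rel=1e-9)

    def test_tuning_returns_grid_member(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        g, bw = lssvm_tune(X, y)
        assert g in (0.1, 1.0, 10.0, 100.0, 1e3, 1e4)
        ratio = bw / median_heuristic(X)
        assert any(np.isclose(ratio, f) for f in (0.25, 0.5, 1.0, 2.0, 4.0))


class TestLooCv:
    def test_zeta_links_stddev_and_rmse(self):
        # reference spread 18.3% with zeta = 3 implies an error of 6.1%
        assert 18.3 / 3.0 == pytest.approx(6.1, abs=1e-12)
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([3.0, -2.0, 1.0, 0.5]) + rng.normal(size=30)
        fit = lambda Xtr, ytr: (lambda Xq: (
            np.atleast_2d(Xq) @ np.linalg.lstsq(Xtr, ytr, rcond=None)[0]))
        res = loo_cv(fit, X, y)
        assert res.zeta == pytest.approx(res.stddev_ref / res.rmse, rel=1e-12)

    def test_predict_the_mean_gives_zeta_near_one(self):
        rng = np.random.default_rng(13)
        y = rng.normal(50.0, 10.0, size=60)
        X = rng.normal(size=(60, 3))  # ignored by the model
        fit = lambda Xtr, ytr: (lambda Xq: np.full(len(np.atleast_2d(Xq)), ytr.mean()))
        res = loo_cv(fit, X, y)
        assert res.zeta == pytest.approx(1.0, abs=0.05)

    def test_perfect_model_capped(self):
        y = np.arange(10.0)
        X = y[:, None]
        fit = lambda Xtr, ytr: (lambda Xq: np.atleast_2d(Xq)[:, 0])
        res = loo_cv(fit, X, y)
        assert res.rmse == 0.0 and res.zeta == ZETA_CAP


class TestKennardStone:
    def test_collinear_extremes_selected_first(self):
        T = np.array([[0.0], [1.0], [2.0], [10.0]])
        sel = kennard_stone_select(T, n_select=2)
        assert set(sel) == {0, 3}

    def test_select_all_returns_all(self):
        T = np.random.default_rng(14).normal(size=(7, 2))
        assert set(kennard_stone_select(T, n_select=7)) == set(range(7))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        T = rng.normal(size=(30, 2))
        mine = kennard_stone_select(T, n_select=10)
        oracle = _oracle_kennard_stone(T, 10)
        assert list(mine) == oracle

    def test_deterministic_under_reruns(self):
        rng = np.random.default_rng(16)
        T = rng.normal(size=(20, 3))
        a = kennard_stone_select(T, fraction=1 / 3)
        b = kennard_stone_select(T, fraction=1 / 3)
        assert list(a) == list(b)
        assert len(a) == 7  # ceil(20/3)


@pytest.fixture(scope="module")
def tiny_study():
    rng = np.random.default_rng(17)
    n, p = 24, 12
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[2], beta[7] = 4.0, -3.0
    y1 = 40.0 + X @ beta + rng.normal(size=n)
    y2 = 30.0 - 0.5 * (X @ beta) + rng.normal(size=n)
    targets = pd.DataFrame({"dH": y1, "dE": y2})
    block = PredictorBlock(X, [float(1480 + 8 * j) for j in range(p)])
    return block, targets


class TestEvaluateAll:
    def test_report_shape_and_zeta_consistency(self, tiny_study):
        block, targets = tiny_study
        rep = evaluate_all({"raw": block}, targets, methods=("aslr", "pls"),
                           splits=("loo", "ks"), selection="global",
                           aslr_max_terms=2, pls_max_lv=5)
        assert len(rep.frame) == 2 * 2 * 1 * 2
        assert rep.check_consistency()
        assert set(rep.frame["split"]) == {"loo", "ks"}

    def test_ks_reference_spread_differs_from_loo(self, tiny_study):
        # the max-min test set is deliberately spread out, so its reference
        # standard deviation generally exceeds the whole-set one
        block, targets = tiny_study
        rep = evaluate_all({"raw": block}, targets[["dH"]], methods=("pls",),
                           splits=("loo", "ks"), selection="global", pls_max_lv=5)
        f = rep.frame.set_index("split")
        assert f.loc["ks", "stddev_ref"] != f.loc["loo", "stddev_ref"]

    def test_strong_ir_absorbers_alone_cannot_predict_planted_helix_model(self):
        # helix content planted on Leu/Pro/Thr/Val/Ala; restricting the
        # predictor block to the 8 strong amide-region absorbers leaves
        # almost no signal, capping zeta near 1
        plant = {"L": 3.3, "P": -4.8, "T": -1.9, "V": -2.3, "A": 1.3}
        aa = "ACDEFGHIKLMNPQRSTVWY"
        strong = list("DERKQNYH")
        zetas_strong, zetas_all = [], []
        for rep in range(3):
            cfg = GeneratorConfig(n_proteins=92, seed=700 + rep)
            comps = sample_compositions(sample_structures(cfg), cfg)
            X = np.array([[c.percent(a) for a in aa] for c in comps])
            rng = np.random.default_rng(800 + rep)
            y = 39.1 + sum(co * X[:, aa.index(r)] for r, co in plant.items())
            y = y + rng.normal(0.0, 5.0, len(y))
            idx = [aa.index(r) for r in strong]
            fit = lambda Xtr, ytr: aslr_fit(
                PredictorBlock(Xtr, list(range(Xtr.shape[1]))), ytr, max_terms=5).predict
            zetas_strong.append(loo_cv(fit, X[:, idx], y).zeta)
            zetas_all.append(loo_cv(fit, X, y).zeta)
        assert np.median(zetas_strong) < 1.35
        assert np.median(zetas_all) > np.median(zetas_strong)
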