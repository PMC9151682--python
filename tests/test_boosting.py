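"""Gradients, leaf weights and splits are checked against finite differences,
grid searches and exhaustive enumeration; training must be deterministic and
its regularized objective monotone."""

import numpy as np
import pytest

from specal import boosting
from specal.boosting import (
    BoostParams,
    best_split,
    fit,
    leaf_weight,
    predict,
    predict_proba,
    predict_raw,
    softmax_grad_hess,
    structure_score,
)


class TestSoftmaxGradHess:
    def test_symmetric_scores(self):
        g, h = softmax_grad_hess(np.array([0]), np.zeros((1, 3)))
        assert np.allclose(g, [[1 / 3 - 1, 1 / 3, 1 / 3]])
        assert np.allclose(h, [[2 / 9, 2 / 9, 2 / 9]])

    def test_confident_limit(self):
        raw = np.array([[30.0, 0.0, 0.0]])
        g, h = softmax_grad_hess(np.array([0]), raw)
        assert np.abs(g).max() < 1e-10
        assert np.abs(h).max() < 1e-10

    def test_matches_finite_differences(self, rng):
        """Central differences of the scalar cross-entropy loss."""
        n, C = 6, 4
        raw = rng.normal(size=(n, C))
        y = rng.integers(0, C, size=n)
        g, h = softmax_grad_hess(y, raw)

        def loss(scores):
            shifted = scores - scores.max(axis=1, keepdims=True)
            p = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
            return -np.log(p[np.arange(n), y]).sum()

        eps = 1e-5
        for i in range(n):
            for c in range(C):
                up, down = raw.copy(), raw.copy()
                up[i, c] += eps
                down[i, c] -= eps
                g_fd = (loss(up) - loss(down)) / (2 * eps)
                h_fd = (loss(up) - 2 * loss(raw) + loss(down)) / eps ** 2
                assert g[i, c] == pytest.approx(g_fd, abs=1e-5)
                assert h[i, c] == pytest.approx(h_fd, abs=1e-4)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(FloatingPointError):
            softmax_grad_hess(np.array([0]), np.array([[np.inf, 0.0]]))


class TestLeafWeight:
    @pytest.mark.parametrize("G,H,lam,expected", [
        (0.0, 5.0, 1.0, 0.0),
        (2.0, 3.0, 1.0, -0.5),
    ])
    def test_closed_form(self, G, H, lam, expected):
        assert leaf_weight(G, H, lam) == pytest.approx(expected)

    def test_minimizes_quadratic_on_grid(self, rng):
        G, H, lam = rng.normal(), abs(rng.normal()) + 0.1, 0.7
        w_star = leaf_weight(G, H, lam)
        grid = np.linspace(w_star - 2, w_star + 2, 20001)
        objective = G * grid + 0.5 * (H + lam) * grid ** 2
        assert abs(grid[np.argmin(objective)] - w_star) < 1e-3


class TestStructureScore:
    def test_cancelling_gradients_leave_only_leaf_penalty(self):
        score = structure_score([0, 0], [1.0, -1.0], [0.5, 0.5],
                                reg_lambda=0.0, gamma=0.3)
        assert score == pytest.approx(0.3)

    def test_two_pure_leaves_vs_mixed_hand_trace(self):
        """4 samples, g = (-1,-1,1,1), h = 1 each, lambda = 1.
        Mixed single leaf: -0.5*0/(4+1) + gamma = gamma.
        Two pure leaves: -0.5*[4/3 + 4/3] + 2*gamma."""
        g = [-1.0, -1.0, 1.0, 1.0]
        h = [1.0, 1.0, 1.0, 1.0]
        mixed = structure_score([0, 0, 0, 0], g, h, 1.0, 0.1)
        split = structure_score([0, 0, 1, 1], g, h, 1.0, 0.1)
        assert mixed == pytest.approx(0.1)
        assert split == pytest.approx(-4 / 3 + 0.2)

    def test_gamma_linear_in_leaf_count(self, rng):
        g, h = rng.normal(size=8), np.full(8, 0.5)
        parts = [0, 0, 1, 1, 2, 2, 3, 3]
        s0 = structure_score(parts, g, h, 1.0, 0.0)
        s1 = structure_score(parts, g, h, 1.0, 0.25)
        assert s1 - s0 == pytest.approx(4 * 0.25)


class TestBestSplit:
    def test_separable_groups_hand_computed(self):
        """Two 1-D groups around 0 and 10, lambda = gamma = 0: split at the
        midpoint with gain 0.5*[G_L^2/H_L + G_R^2/H_R - G^2/H]."""
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        h = np.ones(4)
        feature, threshold, gain = best_split(X, g, h, reg_lambda=0.0,
                                              gamma=0.0)
        assert feature == 0 and threshold == pytest.approx(5.0)
        assert gain == pytest.approx(0.5 * (4 / 2 + 4 / 2 - 0.0))

    def test_gamma_above_gain_stops_growth(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        h = np.ones(4)
        assert best_split(X, g, h, reg_lambda=0.0, gamma=2.5) is None

    def test_constant_features_give_no_split(self):
        X = np.full((5, 3), 1.23)
        assert best_split(X, np.arange(5.0), np.ones(5)) is None

    def test_min_child_weight_blocks_small_children(self):
        X = np.array([[0.0], [10.0], [11.0], [12.0]])
        g = np.array([-3.0, 1.0, 1.0, 1.0])
        h = np.ones(4)
        assert best_split(X, g, h, reg_lambda=0.0,
                          min_child_weight=2.0) is not None
        split = best_split(X, g, h, reg_lambda=0.0, min_child_weight=2.0)
        # the 1-vs-3 split is inadmissible; only 2-vs-2 remains
        assert split[1] == pytest.approx(10.5)

    def test_matches_exhaustive_enumeration(self, rng):
        """Exact agreement with brute force over every (feature, midpoint)
        pair on 50 random small datasets."""
        for _ in range(50):
            n = int(rng.integers(4, 21))
            d = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, d)), 1)  # force ties
            g = rng.normal(size=n)
            h = rng.uniform(0.1, 1.0, size=n)
            lam, gamma = 0.5, 0.05
            best = None
            for f in range(d):
                values = np.unique(X[:, f])
                for lo, hi in zip(values[:-1], values[1:]):
                    thr = 0.5 * (lo + hi)
                    left = X[:, f] <= thr
                    GL, HL = g[left].sum(), h[left].sum()
                    GR, HR = g[~left].sum(), h[~left].sum()
                    gain = 0.5 * (GL ** 2 / (HL + lam) + GR ** 2 / (HR + lam)
                                  - (GL + GR) ** 2 / (HL + HR + lam)) - gamma
                    if gain > 0 and (best is None or gain > best[2] + 1e-12):
                        best = (f, thr, gain)
            got = best_split(X, g, h, reg_lambda=lam, gamma=gamma)
            if best is None:
                assert got is None
            else:
                assert got[0] == best[0]
                assert got[1] == pytest.approx(best[1])
                assert got[2] == pytest.approx(best[2])


class TestFit:
    def _toy(self, rng, n=30):
        X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(4, 1, (n, 4))])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separable_data_reaches_perfect_training_accuracy(self, rng):
        X, y = self._toy(rng)
        params = BoostParams(n_classes=2, n_rounds=10, subsample=1.0,
                             colsample=1.0)
        ensemble = fit(X, y, params)
        assert (predict(ensemble, X) == y).mean() == 1.0

    def test_equal_seeds_give_identical_ensembles(self, rng):
        X, y = self._toy(rng)
        params = BoostParams(n_classes=2, n_rounds=5, subsample=0.7,
                             colsample=0.5, seed=11)
        a, b = fit(X, y, params), fit(X, y, params)
        for ta, tb in zip(a.trees, b.trees):
            assert np.array_equal(ta.value, tb.value)
            assert np.array_equal(ta.threshold, tb.threshold)
        assert a.objective_history == b.objective_history

    def test_objective_non_increasing_full_sample(self, rng):
        X, y = self._toy(rng)
        params = BoostParams(n_classes=2, n_rounds=50, subsample=1.0,
                             colsample=1.0)
        obj = fit(X, y, params).objective_history
        assert np.all(np.diff(obj) <= 1e-9)

    def test_squared_error_single_round_hand_trace(self):
        """6 points, one stump round at learning rate 1: the two leaf values
        are the shrunken residual means -G/(H+lambda)."""
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        params = BoostParams(objective="squared_error", n_rounds=1,
                             max_depth=1, learning_rate=1.0, reg_lambda=1.0,
                             subsample=1.0, colsample=1.0,
                             min_child_weight=0.0)
        ensemble = fit(X, y, params)
        pred = predict(ensemble, X)
        # G_left = -(1+2+3) = -6, H_left = 3 -> w = 6/4 = 1.5
        assert np.allclose(pred[:3], 6 / 4)
        # G_right = -(11+12+13) = -36, H_right = 3 -> w = 36/4 = 9
        assert np.allclose(pred[3:], 36 / 4)

    def test_leaf_weights_satisfy_first_order_condition(self, rng):
        """Every fitted leaf weight equals -G/(H+lambda) for the samples it
        captures (full-sample single round)."""
        X, y = self._toy(rng, n=20)
        params = BoostParams(n_classes=2, n_rounds=1, subsample=1.0,
                             colsample=1.0)
        ensemble = fit(X, y, params)
        g, h = softmax_grad_hess(y, np.zeros((40, 2)))
        for c, tree in enumerate(ensemble.trees):
            leaf_of = _leaf_assignment(tree, X)
            for leaf in np.unique(leaf_of):
                members = leaf_of == leaf
                G, H = g[members, c].sum(), h[members, c].sum()
                assert tree.value[leaf] == pytest.approx(
                    -G / (H + params.reg_lambda), abs=1e-12)

    def test_depth1_stump_is_exhaustive_optimum(self, rng):
        """lambda = gamma = 0, one round, depth 1: the fitted stump matches
        the best stump found by scoring every (feature, threshold) pair
        under the second-order objective."""
        X = rng.normal(size=(15, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=15) > 0).astype(int)
        if np.unique(y).size < 2:
            y[0] = 1 - y[0]
        params = BoostParams(n_classes=2, n_rounds=1, max_depth=1,
                             reg_lambda=0.0, gamma=0.0, subsample=1.0,
                             colsample=1.0, min_child_weight=0.0)
        ensemble = fit(X, y, params)
        g, h = softmax_grad_hess(y, np.zeros((15, 2)))
        tree0 = ensemble.trees[0]
        expected = best_split(X, g[:, 0], h[:, 0], 0.0, 0.0, 0.0)
        assert tree0.feature[0] == expected[0]
        assert tree0.threshold[0] == pytest.approx(expected[1])

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit(X, np.zeros(10, dtype=int), BoostParams(n_classes=2))


def _leaf_assignment(tree, X):
    out = np.empty(X.shape[0], dtype=int)
    for i, x in enumerate(np.atleast_2d(X)):
        node = 0
        while tree.feature[node] != -1:
            node = (tree.left[node] if x[tree.feature[node]] <= tree.threshold[node]
                    else tree.right[node])
        out[i] = node
    return out


class TestPredict:
    def test_zero_round_ensemble_is_uniform(self, rng):
        X = rng.normal(size=(4, 3))
        params = BoostParams(n_classes=5, n_rounds=0)
        ensemble = fit(X, rng.integers(0, 5, 4), params)
        assert np.allclose(predict_proba(ensemble, X), 1 / 5)

    def test_rows_sum_to_one(self, rng):
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(3, 1, (15, 3))])
        y = np.array([0] * 15 + [1] * 15)
        ensemble = fit(X, y, BoostParams(n_classes=2, n_rounds=5))
        p = predict_proba(ensemble, rng.normal(size=(8, 3)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (10, 3))])
        y = np.array([0] * 10 + [1] * 10)
        ensemble = fit(X, y, BoostParams(n_classes=2, n_rounds=3))
        ensemble.save(tmp_path / "model.json")
        back = boosting.BoostedEnsemble.load(tmp_path / "model.json")
        assert np.array_equal(predict_raw(back, X), predict_raw(ensemble, X))

    def test_label_agreement_with_external_gbt(self, rng):
        """Sanity cross-check against an independent gradient-boosting
        implementation on an easy shared task (label agreement, not
        bit-exactness)."""
        xgboost = pytest.importorskip("xgboost")
        X = np.vstack([rng.normal(0, 1, (40, 5)),
                       rng.normal(2.5, 1, (40, 5)),
                       rng.normal(-2.5, 1, (40, 5))])
        y = np.repeat([0, 1, 2], 40)
        params = BoostParams(n_classes=3, n_rounds=30, subsample=1.0,
                             colsample=1.0, min_child_weight=1.0)
        ours = fit(X, y, params)
        theirs = xgboost.XGBClassifier(
            n_estimators=30, max_depth=5, learning_rate=0.1, reg_lambda=1.0,
            tree_method="exact", random_state=0)
        theirs.fit(X, y)
        agreement = (predict(ours, X) == theirs.predict(X)).mean()
        assert agreement >= 0.95
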