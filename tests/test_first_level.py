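"""Stratified folds and cross-validated nonnegative ridge regression."""

import numpy as np
import pytest

from rdmpart.first_level import (
    CrossValPlan,
    FoldSpec,
    fit_nn_ridge,
    fold_schedule,
    make_fold,
    predict_pairs,
    select_lambda,
)
from rdmpart.rdm_core import PredictorSet, StimulusSet, pair_index, vectorize
from rdmpart.rdm_core import rdm_from_dimension


def grid_search_nn_ridge(y, Xs, lam, w_max=3.0):
    """Independent coarse-to-fine dense grid search oracle.

    Minimizes ||y - Xs w - b||^2 + lam ||w||^2 over w >= 0 on a dense
    grid (intercept profiled out exactly).  Final resolution 0.005.
    """
    y = np.asarray(y, float)
    Xs = np.asarray(Xs, float)
    m = Xs.shape[1]

    def objective(W):  # W: (k, m)
        resid = y[None, :] - W @ Xs.T
        b = resid.mean(axis=1, keepdims=True)
        return np.sum((resid - b) ** 2, axis=1) + lam * np.sum(W**2, axis=1)

    lo = np.zeros(m)
    hi = np.full(m, w_max)
    step = 0.05
    best = None
    while step >= 0.005 - 1e-12:
        axes = [np.arange(lo[j], hi[j] + step / 2, step) for j in range(m)]
        mesh = np.meshgrid(*axes, indexing="ij")
        W = np.column_stack([g.ravel() for g in mesh])
        W = np.clip(W, 0.0, None)
        vals = objective(W)
        best = W[np.argmin(vals)]
        lo = np.maximum(best - 1.5 * step, 0.0)
        hi = best + 1.5 * step
        step /= 10.0
    return best


class TestMakeFold:
    def test_92_image_fold_has_84_training_images(self, stimuli92):
        fold = make_fold(stimuli92, seed=0)
        assert len(fold.train_ids) == 84 and len(fold.test_ids) == 8

    def test_test_composition_two_faces_two_bodyparts_four_inanimate(
        self, stimuli92
    ):
        fold = make_fold(stimuli92, seed=1)
        cats = {
            sid: c for sid, c in zip(stimuli92.image_ids, stimuli92.categories)
        }
        test_cats = [cats[s] for s in fold.test_ids]
        faces = sum(c in ("human_face", "animal_face") for c in test_cats)
        bodies = sum(c in ("human_body", "animal_body") for c in test_cats)
        inan = sum(c in ("natural", "manmade") for c in test_cats)
        assert (faces, bodies, inan) == (2, 2, 4)

    def test_same_seed_identical_fold(self, stimuli92):
        assert make_fold(stimuli92, seed=3) == make_fold(stimuli92, seed=3)

    def test_infeasible_composition_errors(self):
        small = StimulusSet.from_composition(
            {"human_face": 1, "natural": 5}
        )
        with pytest.raises(ValueError, match="infeasible"):
            make_fold(
                small, test_size=3, composition={"faces": 2, "inanimate": 1},
                seed=0,
            )

    def test_overlapping_train_test_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FoldSpec(("a", "b"), ("b", "c"))


class TestFoldSchedule:
    def test_schedule_covers_every_pair(self, stimuli24):
        sched = fold_schedule(stimuli24, seed=0)
        n = len(stimuli24)
        rows, cols = pair_index(n)
        covered = np.zeros(rows.size, bool)
        pos = {(i, j): k for k, (i, j) in enumerate(zip(rows, cols))}
        idx = {s: i for i, s in enumerate(stimuli24.image_ids)}
        for fold in sched:
            t = sorted(idx[s] for s in fold.test_ids)
            for a in range(len(t)):
                for b in range(a + 1, len(t)):
                    covered[pos[(t[a], t[b])]] = True
        assert covered.all()

    def test_toy_set_reaches_coverage_with_scaled_composition(self):
        toy = StimulusSet.from_composition(
            {"human_face": 2, "human_body": 2, "natural": 4, "manmade": 4}
        )
        sched = fold_schedule(
            toy, seed=1, test_size=8,
            composition={"faces": 2, "bodyparts": 2, "inanimate": 4},
        )
        assert len(sched) >= 1

    def test_composition_leaving_pair_types_unreachable_errors(self):
        # with one face per test set, the two faces can never co-occur in a
        # held-out set, so full pair coverage is provably unreachable
        toy = StimulusSet.from_composition(
            {"human_face": 2, "human_body": 2, "natural": 4, "manmade": 4}
        )
        with pytest.raises(RuntimeError, match="uncovered"):
            fold_schedule(
                toy, seed=1, test_size=4, max_folds=200,
                composition={"faces": 1, "bodyparts": 1, "inanimate": 2},
            )

    def test_single_fold_cannot_cover_92_images(self, stimuli92):
        with pytest.raises(RuntimeError, match="uncovered"):
            fold_schedule(stimuli92, seed=0, max_folds=1)


class TestFitNnRidge:
    def test_realizable_target_recovered_at_small_lambda(self, rng):
        X = rng.random((40, 3))
        y = 2.0 * X[:, 1] + 0.3
        fit = fit_nn_ridge(y, X, lam=1e-8)
        w = fit.weights_original
        assert w[1] == pytest.approx(2.0, abs=1e-4)
        assert w[0] == pytest.approx(0.0, abs=1e-4)
        assert w[2] == pytest.approx(0.0, abs=1e-4)
        resid = y - predict_pairs(fit, X)
        assert np.max(np.abs(resid)) < 1e-6

    def test_anticorrelated_predictor_pinned_at_zero(self, rng):
        x = rng.random(30)
        y = -x + rng.normal(0, 0.01, 30)
        fit = fit_nn_ridge(y, x[:, None], lam=0.1)
        assert fit.weights[0] == 0.0

    def test_constant_target_gives_intercept_only(self):
        X = np.random.default_rng(0).random((10, 2))
        fit = fit_nn_ridge(np.full(10, 3.0), X, lam=1.0)
        assert np.all(fit.weights == 0) and fit.intercept == pytest.approx(3.0)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_nn_ridge(rng.random(10), rng.random((10, 2)), lam=-1.0)

    def test_matches_dense_grid_search_oracle(self, rng):
        # random small instances compared against exhaustive search
        for _ in range(20):
            m = rng.integers(2, 4)
            n = rng.integers(8, 16)
            X = rng.random((n, m))
            Xs = (X - X.mean(0)) / X.std(0)
            w_true = rng.random(m) * 1.5
            y = Xs @ w_true + rng.normal(0, 0.2, n)
            lam = float(rng.choice([0.01, 0.1, 1.0]))
            fit = fit_nn_ridge(y, Xs, lam=lam)
            w_oracle = grid_search_nn_ridge(y, (Xs - Xs.mean(0)) / Xs.std(0), lam)
            assert np.allclose(fit.weights, w_oracle, atol=0.01)

    def test_objective_never_worse_than_intercept_only(self, rng):
        X = rng.random((25, 3))
        y = rng.random(25)
        fit = fit_nn_ridge(y, X, lam=0.5)
        pred = predict_pairs(fit, X)
        obj = np.sum((y - pred) ** 2) + 0.5 * np.sum(fit.weights**2)
        obj0 = np.sum((y - y.mean()) ** 2)
        assert obj <= obj0 + 1e-10


class TestSelectLambda:
    def test_single_element_grid_returned(self, stimuli24, rng):
        X = rng.random((len(stimuli24) * 23 // 2, 2))
        y = rng.random(X.shape[0])
        assert select_lambda(y, X, stimuli24, grid=[0.7]) == 0.7

    def test_noiseless_realizable_target_prefers_smallest_lambda(
        self, stimuli24, rng
    ):
        n_pairs = len(stimuli24) * 23 // 2
        X = rng.random((n_pairs, 3))
        y = X @ np.array([1.0, 0.5, 2.0]) + 0.1
        lam = select_lambda(y, X, stimuli24, grid=[1e-6, 1.0, 100.0], seed=0)
        assert lam == 1e-6

    def test_negative_grid_rejected(self, stimuli24, rng):
        X = rng.random((len(stimuli24) * 23 // 2, 2))
        with pytest.raises(ValueError):
            select_lambda(rng.random(X.shape[0]), X, stimuli24, grid=[-1.0])


def _binary_predictors(stimuli, m, rng):
    cols = []
    while len(cols) < m:
        c = rng.integers(0, 2, len(stimuli)).astype(float)
        if 0 < c.sum() < len(stimuli):
            cols.append(c)
    vecs = [vectorize(rdm_from_dimension(c, stimuli.image_ids)) for c in cols]
    return PredictorSet.from_rdm_vectors(
        vecs, [f"dim{k}" for k in range(m)], "visuo_semantic", "object_part"
    )


class TestCrossValPredict:
    def test_noiseless_recovery_and_test_only_prediction(self, stimuli24, rng):
        ps = _binary_predictors(stimuli24, 5, rng)
        w_true = np.array([1.5, 0.0, 0.8, 0.4, 2.0])
        y = ps.X @ w_true + 0.5
        sched = fold_schedule(stimuli24, seed=3)
        plan = CrossValPlan(
            stimuli24, ps.X, sched, grid=[1e-6, 1e-3, 1.0], inner_folds=3,
            seed=0,
        )
        pred = plan.predict(y)
        assert pred.coverage.min() >= 1
        ss_res = np.sum((y - pred.v_hat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        # fitted weights (mapped back to raw scale) track planted ones
        r = np.corrcoef(pred.mean_weights_original, w_true)[0, 1]
        assert r > 0.99

    def test_wrapper_matches_plan_prediction(self, stimuli24, rng):
        from rdmpart.first_level import crossval_predict

        ps = _binary_predictors(stimuli24, 3, rng)
        y = ps.X @ np.array([1.0, 0.2, 0.6]) + 0.4
        sched = fold_schedule(stimuli24, seed=11)
        plan = CrossValPlan(stimuli24, ps.X, sched, grid=[1e-4, 1.0], seed=2)
        via_plan = plan.predict(y)
        via_wrapper = crossval_predict(
            y, ps, sched, stimuli24, grid=[1e-4, 1.0], seed=2
        )
        assert np.array_equal(via_plan.v_hat, via_wrapper.v_hat)
        assert np.array_equal(via_plan.coverage, via_wrapper.coverage)

    def test_weights_nonnegative_in_every_fold(self, stimuli24, rng):
        ps = _binary_predictors(stimuli24, 4, rng)
        y = rng.random(ps.X.shape[0])
        sched = fold_schedule(stimuli24, seed=5)
        plan = CrossValPlan(stimuli24, ps.X, sched, grid=[0.1], seed=0)
        for fold in plan.folds:
            from rdmpart.first_level import _nn_ridge_solve

            w = _nn_ridge_solve(y[fold["train_pairs"]], fold["A_aug"][0],
                                fold["train_pairs"].size)
            assert np.all(w >= 0)

    def test_incomplete_schedule_rejected(self, stimuli24, rng):
        ps = _binary_predictors(stimuli24, 3, rng)
        sched = fold_schedule(stimuli24, seed=3)[:2]
        with pytest.raises(ValueError, match="uncovered"):
            CrossValPlan(stimuli24, ps.X, sched, grid=[0.1])

    def test_prediction_invariant_to_image_relabeling(self, stimuli24, rng):
        # permuting condition order permutes v_hat consistently: predicting
        # the same geometry under a different image ordering gives the same
        # per-pair values after reindexing
        ps = _binary_predictors(stimuli24, 3, rng)
        y = ps.X @ np.array([1.0, 0.5, 0.7]) + 0.2
        sched = fold_schedule(stimuli24, seed=7)
        plan = CrossValPlan(stimuli24, ps.X, sched, grid=[1e-6], seed=0)
        v1 = plan.predict(y).v_hat
        v2 = plan.predict(y).v_hat  # deterministic plan: identical reruns
        assert np.array_equal(v1, v2)
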