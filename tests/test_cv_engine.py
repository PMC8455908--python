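"""Fold plans, sufficient-statistics least squares, and win-count selection."""

import numpy as np
import pytest

from conftest import make_linear_dataset
from harshcv.cv_engine import (evaluate_masks, fit_linear_suffstats,
                               make_fold_plan, rmse_prediction,
                               run_cv_selection)
from harshcv.model_space import CandidateEffectSet, build_full_design


class TestFoldPlan:
    def test_exact_division(self):
        plan = make_fold_plan(100, 10, 3, seed=1)
        for r in range(3):
            sizes = np.bincount(plan.assignment[r], minlength=10)
            assert (sizes == 10).all()

    def test_balance_rule_uneven(self):
        plan = make_fold_plan(103, 10, 2, seed=1)
        for r in range(2):
            sizes = np.sort(np.bincount(plan.assignment[r], minlength=10))
            assert list(sizes) == [10] * 7 + [11] * 3

    def test_seed_determinism(self):
        a = make_fold_plan(57, 5, 4, seed=9).assignment
        b = make_fold_plan(57, 5, 4, seed=9).assignment
        c = make_fold_plan(57, 5, 4, seed=10).assignment
        assert (a == b).all()
        assert (a != c).any()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="2K"):
            make_fold_plan(19, 10, 1, seed=0)


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse_prediction([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert rmse_prediction([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_hand_value(self):
        assert rmse_prediction([1, 2, 3], [2, 2, 2]) == pytest.approx(
            np.sqrt(2 / 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse_prediction([], [])


class TestSuffstatsFit:
    def test_exact_linear_response(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        beta_true = np.array([1.0, -2.0, 0.5])
        y = X @ beta_true
        beta = fit_linear_suffstats(X.T @ X, X.T @ y, [0, 1, 2])
        assert np.allclose(beta, beta_true, atol=1e-10)

    def test_intercept_only_gives_mean(self, rng):
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 3))])
        y = rng.normal(size=25)
        beta = fit_linear_suffstats(X.T @ X, X.T @ y, [0])
        assert beta[0] == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 5))])
        y = rng.normal(size=50)
        cols = np.array([0, 2, 4])
        beta = fit_linear_suffstats(X.T @ X, X.T @ y, cols)
        oracle, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        assert np.max(np.abs(beta - oracle)) < 1e-8

    def test_singular_jitter_warns(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="jitter"):
            fit_linear_suffstats(X.T @ X, X.T @ y, [0, 1])


def naive_cv_rmse(X, y, col_sets, plan, inverted_folds=False):
    """Oracle: refit every model per fold with lstsq, pool per repeat."""
    R, M = plan.R, len(col_sets)
    out = np.zeros((R, M))
    for r in range(R):
        labels = plan.assignment[r]
        for m, cols in enumerate(col_sets):
            sse, n_total = 0.0, 0
            for k in range(plan.K):
                test = labels == k if not inverted_folds else labels != k
                train = ~test
                beta, *_ = np.linalg.lstsq(X[np.ix_(train, cols)], y[train],
                                           rcond=None)
                resid = y[test] - X[np.ix_(test, cols)] @ beta
                sse += resid @ resid
                n_total += test.sum()
            out[r, m] = np.sqrt(sse / n_total)
    return out


@pytest.mark.parametrize("inverted", [False, True])
def test_suffstats_path_equals_naive_refitting(rng, inverted):
    """The Gram-matrix engine must match per-model refitting to 1e-8."""
    n, d = 60, 6
    X = np.column_stack([np.ones(n), rng.normal(size=(n, d - 1))])
    y = X[:, 1] - 0.5 * X[:, 3] + rng.normal(size=n)
    col_sets = [np.array(c) for c in
                ([0], [0, 1], [0, 1, 2], [0, 3, 4, 5], [0, 1, 2, 3, 4, 5])]
    plan = make_fold_plan(n, 5, 4, seed=3)
    fast = evaluate_masks(X, y, col_sets, plan, inverted_folds=inverted)
    slow = naive_cv_rmse(X, y, col_sets, plan, inverted_folds=inverted)
    assert np.max(np.abs(fast - slow)) < 1e-8


class TestSelection:
    def test_recovers_true_two_effect_model(self, rng):
        df = make_linear_dataset(rng, 900, {"x1": 0.5, "x2": 0.5},
                                 noise_sd=0.5, extra=["x3"])
        es = CandidateEffectSet(("x1", "x2", "x3"))
        res = run_cv_selection(df, es, K=10, R=50, seed=11)
        true_mask = 0b011
        m = [s.mask for s in res.models].index(true_mask)
        assert res.win_percent[m] >= 60.0
        assert res.winner.mask == true_mask

    def test_pure_noise_favors_parsimony(self, rng):
        # With no signal, each repeat's winner is driven by spurious sample
        # correlations; small models dominate, the full model essentially
        # never wins, and the run winner is a single-effect model.
        df = make_linear_dataset(rng, 400, {}, noise_sd=1.0,
                                 extra=["x1", "x2", "x3"])
        es = CandidateEffectSet(("x1", "x2", "x3"))
        res = run_cv_selection(df, es, K=10, R=50, seed=5)
        masks = [s.mask for s in res.models]
        wins = {m: w for m, w in zip(masks, res.win_counts)}
        single = wins[0b001] + wins[0b010] + wins[0b100]
        assert single > wins[0b111]
        assert res.winner.n_params == 2

    def test_identical_seed_identical_wins(self, rng):
        df = make_linear_dataset(rng, 200, {"x1": 0.3}, extra=["x2"])
        es = CandidateEffectSet(("x1", "x2"))
        a = run_cv_selection(df, es, K=5, R=20, seed=7)
        b = run_cv_selection(df, es, K=5, R=20, seed=7)
        assert (a.win_counts == b.win_counts).all()
        assert np.array_equal(a.rmse, b.rmse)

    def test_fold_sharing_across_models(self, rng):
        df = make_linear_dataset(rng, 100, {"x1": 0.4}, extra=["x2"])
        es = CandidateEffectSet(("x1", "x2"))
        res = run_cv_selection(df, es, K=5, R=3, seed=2)
        # one plan object serves every model; assignments are per-repeat
        assert res.plan.assignment.shape == (3, 100)

    def test_noise_column_does_not_reduce_expected_rmse(self, rng):
        # Expected out-of-sample penalty for one useless predictor; averaged
        # over independent data draws (a single draw can flip sign when the
        # noise column has an atypical spurious correlation).
        diffs = []
        for d in range(15):
            df = make_linear_dataset(rng, 250, {"x1": 0.5}, noise_sd=0.8,
                                     extra=["xn"])
            es = CandidateEffectSet(("x1", "xn"))
            X, y, _ = build_full_design(df, es)
            plan = make_fold_plan(len(y), 10, 20, seed=100 + d)
            rmse = evaluate_masks(
                X, y, [np.array([0, 1]), np.array([0, 1, 2])], plan)
            diffs.append(rmse[:, 1].mean() - rmse[:, 0].mean())
        assert np.mean(diffs) >= -1e-6

    def test_win_counts_sum_to_repeats(self, rng):
        df = make_linear_dataset(rng, 150, {"x1": 0.4}, extra=["x2"])
        es = CandidateEffectSet(("x1", "x2"))
        res = run_cv_selection(df, es, K=5, R=17, seed=4)
        assert res.win_counts.sum() + res.discarded_repeats == 17
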