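"""Sparse-group-lasso solver, consistent-grid tuning, performance, retention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import admm_sparse_group_lasso, random_sgl_instance, sgl_objective
from xtwas.train import (
    GeneModel,
    HyperParamGrid,
    ModelPerformance,
    default_grid,
    evaluate_performance,
    fit_sparse_group_lasso,
    kkt_violation,
    lambda_max,
    retain_models,
    select_cis_snps,
    tune_consistent_grid,
)


def _make_model(r, p):
    return GeneModel(gene="G", tissue="T", snp_ids=["rs1"], chrom=["1"],
                     pos=[100], effect_allele=["A"], other_allele=["G"],
                     weights=np.array([0.1]),
                     performance=ModelPerformance(r=r, p=p, n_eval=100))


class TestCisWindow:
    def test_boundaries_closed(self):
        import pandas as pd

        meta = pd.DataFrame({"pos": [4_989_999, 4_990_000, 5_020_000, 5_020_001],
                             "snp_id": list("abcd")})
        idx = select_cis_snps(5_000_000, 5_010_000, meta, window=10_000)
        assert list(idx) == [1, 2]

    def test_exact_window_edge_included(self):
        import pandas as pd

        meta = pd.DataFrame({"pos": [4_000_000, 3_999_999], "snp_id": ["a", "b"]})
        idx = select_cis_snps(5_000_000, 5_010_000, meta, window=1_000_000)
        assert list(idx) == [0]


class TestSolver:
    def test_lambda_max_zeroes_all_weights(self, rng):
        X_list, y_list, *_ = random_sgl_instance(rng)
        lmax = lambda_max(X_list, y_list)
        fit = fit_sparse_group_lasso(X_list, y_list, lmax * 1.0001, 0.0)
        assert np.all(fit.weights == 0.0)

    def test_unpenalized_single_tissue_equals_ols(self, rng):
        n, p = 60, 5
        X = rng.standard_normal((n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        y -= y.mean()
        fit = fit_sparse_group_lasso([X], [y], 0.0, 0.0, tol=1e-14, max_iter=200_000)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.weights[:, 0], ols, atol=1e-6)

    def test_toy_instance_matches_admm_oracle(self, rng):
        """3 SNPs x 2 tissues at lambda1 = lambda2 = 0.05."""
        n = 30
        X_list, y_list = [], []
        for _ in range(2):
            X = rng.standard_normal((n, 3))
            X = (X - X.mean(0)) / X.std(0)
            y = X[:, 0] * 0.5 + rng.standard_normal(n)
            X_list.append(X)
            y_list.append(y - y.mean())
        fit = fit_sparse_group_lasso(X_list, y_list, 0.05, 0.05,
                                     tol=1e-14, max_iter=100_000)
        B_oracle = admm_sparse_group_lasso(X_list, y_list, 0.05, 0.05)
        f_impl = sgl_objective(fit.weights, X_list, y_list, 0.05, 0.05)
        f_oracle = sgl_objective(B_oracle, X_list, y_list, 0.05, 0.05)
        assert abs(f_impl - f_oracle) < 1e-6
        np.testing.assert_allclose(fit.weights, B_oracle, atol=1e-4)

    def test_objective_trace_monotone_and_kkt(self, rng):
        for _ in range(10):
            X_list, y_list, lam1, lam2 = random_sgl_instance(rng)
            fit = fit_sparse_group_lasso(X_list, y_list, lam1, lam2,
                                         tol=1e-12, max_iter=50_000)
            trace = np.array(fit.objective_trace)
            assert np.all(np.diff(trace) <= 0)
            assert kkt_violation(fit.weights, X_list, y_list, lam1, lam2) < 1e-4

    def test_non_finite_input_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.r_[np.nan, np.zeros(9)]
        with pytest.raises(ValueError, match="non-finite"):
            fit_sparse_group_lasso([X], [y], 0.1, 0.1)

    def test_max_iter_sets_warning_flag_not_exception(self, rng):
        X_list, y_list, lam1, lam2 = random_sgl_instance(rng)
        fit = fit_sparse_group_lasso(X_list, y_list, lam1 * 1e-3, lam2 * 1e-3,
                                     tol=1e-16, max_iter=3)
        assert not fit.converged


class TestTuning:
    def test_single_pair_grid_selected_with_full_oof(self, rng):
        X_list, y_list, lam1, lam2 = random_sgl_instance(rng, t_max=2)
        grid = HyperParamGrid(pairs=((lam1, lam2),), n_folds=5)
        sel, oof, _ = tune_consistent_grid(X_list, y_list, grid, seed=1)
        assert sel == (lam1, lam2)
        for t, y in enumerate(y_list):
            assert np.all(np.isfinite(oof[t]))
            assert len(oof[t]) == len(y)

    def test_tie_rule_prefers_sparser_pair(self, rng):
        # both pairs exceed lambda_max, so every fit is all-zero and the
        # validation errors tie exactly; the larger (sparser) pair must win
        X_list, y_list, *_ = random_sgl_instance(rng, t_max=1)
        lmax = lambda_max(X_list, y_list)
        grid = HyperParamGrid(pairs=((lmax * 2, 0.0), (lmax * 3, 0.0)))
        sel, _, err = tune_consistent_grid(X_list, y_list, grid, seed=1)
        assert err[0] == err[1]
        assert sel == (lmax * 3, 0.0)

    def test_duplicate_pair_selection_deterministic(self, rng):
        X_list, y_list, *_ = random_sgl_instance(rng, t_max=1)
        lmax = lambda_max(X_list, y_list)
        grid = HyperParamGrid(pairs=((lmax * 2, 0.0), (lmax * 2, 0.0)))
        sel, _, err = tune_consistent_grid(X_list, y_list, grid, seed=1)
        assert err[0] == err[1]
        assert sel == (lmax * 2, 0.0)

    def test_noise_selects_heavy_shrinkage(self):
        """With pure-noise expression the heaviest penalties win the CV."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rr = np.random.default_rng(rep)
            n, p = 60, 5
            X_list, y_list = [], []
            for _ in range(2):
                X = rr.standard_normal((n, p))
                X = (X - X.mean(0)) / X.std(0)
                y = rr.standard_normal(n)
                X_list.append(X)
                y_list.append(y - y.mean())
            grid = default_grid(X_list, y_list, n_lambda=4)
            sel, _, _ = tune_consistent_grid(X_list, y_list, grid, seed=rep)
            ladder = sorted({l1 for l1, _ in grid.pairs}, reverse=True)
            if sel[0] == ladder[0] or sel[1] == ladder[0]:
                hits += 1
        assert hits >= 0.8 * n_rep


class TestPerformance:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(50)
        perf = evaluate_performance(y, y)
        assert perf.r == 1.0 and perf.p == 0.0

    def test_r_boundary_case_matches_t_distribution_oracle(self):
        """r = 0.1 at n = 205 gives p ~ 0.15 — above the retention cut."""
        n = 205
        t = 0.1 * np.sqrt((n - 2) / (1 - 0.01))
        p_expected = 2 * stats.t.sf(t, df=n - 2)
        # construct vectors with exactly r = 0.1 via a two-column rotation
        rng = np.random.default_rng(0)
        a = rng.standard_normal(n)
        a = (a - a.mean()) / a.std()
        b = rng.standard_normal(n)
        b -= b.mean()
        b -= a * np.dot(a, b) / np.dot(a, a)  # zero-mean and orthogonal to a
        b /= b.std()
        y = 0.1 * a + np.sqrt(1 - 0.01) * b
        perf = evaluate_performance(a, y)
        assert perf.r == pytest.approx(0.1, abs=1e-6)
        assert perf.p == pytest.approx(p_expected, rel=1e-6)
        assert p_expected > 0.05

    def test_constant_predictions_degenerate(self):
        perf = evaluate_performance(np.zeros(30), np.random.default_rng(1).standard_normal(30))
        assert perf.r == 0.0 and perf.p == 1.0 and perf.r2 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_performance(np.zeros(5), np.zeros(6))


class TestRetention:
    def test_rule_over_three_cases(self):
        models = [_make_model(0.1, 0.04), _make_model(0.1, 0.06),
                  _make_model(-0.5, 1e-9)]
        kept, summary = retain_models(models)
        assert len(kept) == 1
        assert kept[0].performance.p == 0.04
        assert summary.loc[0, "n_retained"] == 1

    def test_clear_accept_and_r_boundary_reject(self):
        kept, _ = retain_models([_make_model(0.30, 1e-4), _make_model(0.099, 1e-6)])
        assert len(kept) == 1 and kept[0].performance.r == 0.30

    def test_r2_floor_count(self):
        _, summary = retain_models([_make_model(0.1, 0.2), _make_model(0.05, 0.5),
                                    _make_model(-0.9, 1e-9)])
        # r2 is defined as 0 for negative r, so only r = 0.1 clears 0.01
        assert summary.loc[0, "n_r2_ge_0.01"] == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_solver_objective_never_increases(seed):
    rng = np.random.default_rng(seed)
    X_list, y_list, lam1, lam2 = random_sgl_instance(rng, p_max=6, t_max=2, n=25)
    fit = fit_sparse_group_lasso(X_list, y_list, lam1, lam2, tol=1e-10)
    assert np.all(np.diff(fit.objective_trace) <= 0)
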