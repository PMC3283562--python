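import numpy as np
import pytest

from sparsesca import (
    F_GRID_DATA_ANALYSIS,
    F_GRID_SIMULATION,
    FractionGrid,
    PenaltyConfig,
    SolverOptions,
    filter_solutions,
    lambda_from_fraction,
    ordinary_sca,
    run_grid,
)
from sparsesca.tuning import SolutionSummary, reference_penalty_norm, summaries_to_frame

from conftest import make_correlated_data, make_data


class TestLambdaFromFraction:
    def test_zero_fraction_gives_zero_lambda(self, small_data):
        W_ref, *_ = ordinary_sca(small_data, 2)
        assert lambda_from_fraction(0.0, small_data, W_ref, "lasso") == 0.0

    def test_linear_in_f_and_inverse_in_norm(self, small_data):
        W_ref, *_ = ordinary_sca(small_data, 2)
        lam1 = lambda_from_fraction(0.1, small_data, W_ref, "lasso")
        lam5 = lambda_from_fraction(0.5, small_data, W_ref, "lasso")
        assert np.isclose(lam5, 5 * lam1)
        nu = reference_penalty_norm(W_ref, "lasso", small_data.blocks)
        # doubling the reference norm halves lambda
        assert np.isclose(
            lambda_from_fraction(0.1, small_data, 2 * W_ref, "lasso"), lam1 / 2
        )
        assert np.isclose(lam1, 0.1 * small_data.n_variables / nu)

    def test_preprocessed_total_ss_is_column_count(self):
        data = make_data(30, 28, (144, 44))
        W_ref, *_ = ordinary_sca(data, 3)
        nu = reference_penalty_norm(W_ref, "ridge", data.blocks)
        lam = lambda_from_fraction(0.2, data, W_ref, "ridge")
        assert np.isclose(lam, 188.0 * 0.2 / nu)

    def test_zero_reference_norm_errors(self, small_data):
        with pytest.raises(ValueError, match="zero"):
            lambda_from_fraction(0.1, small_data, np.zeros((7, 2)), "lasso")

    def test_standard_grids(self):
        assert F_GRID_DATA_ANALYSIS == (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 0.2, 0.5, 1.0)
        assert F_GRID_SIMULATION == (0.0, 1e-3, 0.1, 0.5, 10.0)


class TestFractionGrid:
    def test_expansion_counts(self):
        g = FractionGrid("lasso", {"lasso": F_GRID_DATA_ANALYSIS}, n_components=2)
        assert len(list(g.points())) == 8
        g2 = FractionGrid(
            "elastic_net",
            {"lasso": (0.1, 0.5), "ridge": (0.0, 0.1, 0.2)},
            n_components=2,
        )
        assert len(list(g2.points())) == 6

    def test_rejects_foreign_penalty(self):
        with pytest.raises(ValueError):
            FractionGrid("lasso", {"group": (0.1,)})


class TestRunGrid:
    def test_f_zero_matches_svd_fit(self):
        data = make_data(31, 25, (5, 4))
        *_, fit_svd, _ = ordinary_sca(data, 2)
        grid = FractionGrid("lasso", {"lasso": (0.0,)}, n_components=2)
        out = run_grid(data, grid)
        assert len(out) == 1
        assert abs(out[0].fit - fit_svd) < 1e-8
        assert out[0].overall_zero_pct == 0.0

    def test_deterministic_reproduction(self):
        data = make_correlated_data(32, 20, (6, 4))
        grid = FractionGrid("elastic_net", {"lasso": (0.1,), "ridge": (0.01,)},
                            n_components=2)
        opts = SolverOptions(seed=3, max_iter=300, tol=1e-10)
        a = summaries_to_frame(run_grid(data, grid, opts))
        b = summaries_to_frame(run_grid(data, grid, opts))
        assert a.equals(b)

    def test_failures_recorded_not_raised(self):
        # f = 0 with more variables than samples: the weights model is
        # underdetermined and the cell must fail gracefully
        data = make_data(33, 6, (5, 5))
        grid = FractionGrid("lasso", {"lasso": (0.0, 0.05)}, n_components=2)
        out = run_grid(data, grid)
        assert out[0].failed and "ridge" in out[0].error
        assert not out[1].failed

    def test_fit_decreases_and_zeros_increase_with_f(self):
        """Averaged over seeds, stronger penalties lose fit and gain
        sparsity."""
        fs = (0.0, 0.05, 0.3, 0.8)
        fits = np.zeros(len(fs))
        zeros = np.zeros(len(fs))
        n_seeds = 5
        for seed in range(n_seeds):
            data = make_correlated_data(40 + seed, 30, (6, 4))
            grid = FractionGrid("lasso", {"lasso": fs}, n_components=2)
            out = run_grid(data, grid, SolverOptions(max_iter=500, tol=1e-10))
            fits += np.array([s.fit for s in out]) / n_seeds
            zeros += np.array([s.overall_zero_pct for s in out]) / n_seeds
        assert np.all(np.diff(fits) <= 1e-9)
        assert np.all(np.diff(zeros) >= -1e-9)

    def test_lasso_fits_better_than_elitist_at_matched_sparsity(self):
        """At comparable zero percentages the unstructured lasso fits at
        least as well as the block-constrained elitist lasso."""
        wins = 0
        comparisons = 0
        for seed in range(3):
            data = make_correlated_data(60 + seed, 30, (6, 4))
            opts = SolverOptions(max_iter=500, tol=1e-10)
            fs = (0.01, 0.05, 0.1, 0.3, 0.5, 1.0)
            lasso = run_grid(
                data, FractionGrid("lasso", {"lasso": fs}, n_components=2), opts
            )
            elitist = run_grid(
                data,
                FractionGrid("elitist_lasso", {"elitist": fs}, n_components=2),
                opts,
            )
            for e in elitist:
                if e.overall_zero_pct == 0 or e.overall_zero_pct >= 100:
                    continue
                matched = [
                    l for l in lasso
                    if abs(l.overall_zero_pct - e.overall_zero_pct) <= 10
                ]
                if matched:
                    comparisons += 1
                    if max(l.fit for l in matched) >= e.fit - 1e-6:
                        wins += 1
        assert comparisons > 0
        assert wins == comparisons


def _summary(fit, per_comp_pct, per_block_pct, per_bc_pct):
    return SolutionSummary(
        preset="sparse_group_lasso_ridge",
        model="weights",
        n_components=len(per_comp_pct),
        fractions={},
        lambdas={},
        fit=fit,
        overall_zero_pct=float(np.mean(per_comp_pct)),
        per_component_zero_counts=np.asarray(per_comp_pct),
        per_component_zero_pct=np.asarray(per_comp_pct, dtype=float),
        per_block_zero_pct=np.asarray(per_block_pct, dtype=float),
        per_block_component_zero_pct=np.asarray(per_bc_pct, dtype=float),
    )


class TestFilterSolutions:
    def test_low_fit_dropped(self):
        s = _summary(0.39, [60.0, 70.0], [65.0, 62.0], [[60, 70], [70, 60]])
        assert filter_solutions([s]) == []
        assert s.fit_below_threshold
        s2 = _summary(0.41, [60.0, 70.0], [65.0, 62.0], [[100, 60], [60, 100]])
        assert filter_solutions([s2]) == [s2]
        assert not any(
            [s2.has_all_zero_component, s2.has_mixed_block_component,
             s2.fit_below_threshold, s2.insufficient_block_sparsity]
        )

    def test_all_zero_component_dropped(self):
        s = _summary(0.6, [100.0, 60.0], [75.0, 70.0], [[100, 60], [100, 60]])
        assert filter_solutions([s]) == []
        assert s.has_all_zero_component

    def test_block_exclusivity_optional(self):
        s = _summary(0.6, [60.0, 70.0], [65.0, 62.0], [[60, 70], [70, 60]])
        assert filter_solutions([s], block_exclusive=True) == []
        assert s.has_mixed_block_component
        assert filter_solutions([s], block_exclusive=False) == [s]

    def test_insufficient_block_sparsity_dropped(self):
        s = _summary(0.6, [60.0, 55.0], [40.0, 70.0], [[100, 30], [50, 100]])
        assert filter_solutions([s], block_exclusive=False) == []
        assert s.insufficient_block_sparsity

    def test_rules_are_order_invariant(self):
        good = _summary(0.5, [60.0, 60.0], [60.0, 60.0], [[100, 60], [60, 100]])
        bad_fit = _summary(0.1, [60.0, 60.0], [60.0, 60.0], [[100, 60], [60, 100]])
        bad_zero = _summary(0.5, [100.0, 60.0], [80.0, 60.0], [[100, 60], [100, 60]])
        for order in ([good, bad_fit, bad_zero], [bad_zero, good, bad_fit]):
            assert filter_solutions(list(order)) == [good]
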