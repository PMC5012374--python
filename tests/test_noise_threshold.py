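"""The correlation-window threshold: each operation against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cellvar.io import ExpressionMatrix
from cellvar.noise_threshold import (
    ThresholdConfig,
    WindowTestResult,
    bin_genes_by_mean,
    filter_zero_genes,
    run_noise_threshold,
    select_reference_genes,
    select_threshold,
    window_correlation_distribution,
)
from cellvar.noise_threshold import test_window_against_baseline as window_test
from cellvar.simulate import SimulationConfig, simulate_matrix


def _matrix_with_zero_counts(zero_counts, n_cells):
    rows = []
    for i, z in enumerate(zero_counts):
        row = np.full(n_cells, 5.0 + i)
        row[:z] = 0.0
        rows.append(row)
    return ExpressionMatrix(
        [f"g{i}" for i in range(len(zero_counts))],
        [f"c{j}" for j in range(n_cells)],
        np.array(rows),
    )


class TestZeroFilter:
    def test_thirty_five_or_more_zeros_discarded(self):
        matrix = _matrix_with_zero_counts([35, 34], n_cells=39)
        kept = filter_zero_genes(matrix, 35)
        assert kept.gene_ids == ["g1"]

    def test_all_zero_gene_discarded_at_cell_count(self):
        matrix = _matrix_with_zero_counts([39, 38], n_cells=39)
        kept = filter_zero_genes(matrix, 39)
        assert kept.gene_ids == ["g1"]  # one non-zero value suffices

    def test_matches_brute_force_zero_count(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(0.7, size=(50, 12)).astype(float)
        matrix = ExpressionMatrix(
            [f"g{i}" for i in range(50)], [f"c{j}" for j in range(12)], values
        )
        for cutoff in (1, 5, 12):
            kept = set(filter_zero_genes(matrix, cutoff).gene_ids)
            expected = {
                g for g, row in zip(matrix.gene_ids, values) if (row == 0).sum() < cutoff
            }
            assert kept == expected


class TestReferenceSelection:
    def test_strictly_above_threshold(self):
        matrix = ExpressionMatrix(
            ["at", "above"],
            ["c1", "c2"],
            np.array([[150.0, 200.0], [151.0, 151.0]]),
        )
        assert select_reference_genes(matrix, 150.0) == {"above"}

    def test_matches_brute_force_on_minima(self, toy_matrix):
        refs = select_reference_genes(toy_matrix, 1.5)
        expected = {
            g
            for g, row in zip(toy_matrix.gene_ids, toy_matrix.values)
            if row.min() > 1.5
        }
        assert refs == expected == {"g3"}

    def test_empty_reference_set_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError, match="ref_min_fpkm"):
            select_reference_genes(toy_matrix, 1e6)


class TestBinning:
    @staticmethod
    def _matrix(n):
        values = np.tile(np.arange(1.0, n + 1.0)[:, None], (1, 2))
        return ExpressionMatrix([f"g{i:05d}" for i in range(n)], ["c1", "c2"], values)

    def test_remainder_pooled_into_lowest_window(self):
        windows = bin_genes_by_mean(self._matrix(2500), 1000)
        assert [len(w) for w in windows] == [1500, 1000]
        # the lowest window holds the lowest means
        assert windows[0][0] == "g00000" and windows[1][-1] == "g02499"

    def test_exact_division(self):
        windows = bin_genes_by_mean(self._matrix(2000), 1000)
        assert [len(w) for w in windows] == [1000, 1000]

    def test_ties_broken_by_gene_id_and_row_order_irrelevant(self):
        values = np.ones((6, 2))
        ids = ["b", "a", "d", "c", "f", "e"]
        m1 = ExpressionMatrix(ids, ["c1", "c2"], values)
        m2 = ExpressionMatrix(ids[::-1], ["c1", "c2"], values)
        assert bin_genes_by_mean(m1, 3) == bin_genes_by_mean(m2, 3) == [
            ["a", "b", "c"],
            ["d", "e", "f"],
        ]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            bin_genes_by_mean(self._matrix(5), 3)


class TestWindowCorrelations:
    def test_matches_pairwise_pearson_oracle(self, toy_matrix):
        corrs, dropped = window_correlation_distribution(
            toy_matrix, ["g1", "g2"], ["g4", "g3", "g1"]
        )
        assert dropped == 2  # g3 is constant: one dropped pair per window gene
        expected = sorted(
            sps.pearsonr(toy_matrix.row(w), toy_matrix.row(r))[0]
            for w in ("g1", "g2")
            for r in ("g4", "g1")
        )
        np.testing.assert_allclose(sorted(corrs), expected, atol=1e-12)

    def test_identical_vectors_correlate_at_one(self, toy_matrix):
        corrs, _ = window_correlation_distribution(toy_matrix, ["g1", "g4"], ["g1", "g2"])
        assert corrs.max() == pytest.approx(1.0)


class TestWindowTest:
    def test_identical_distributions_not_kept(self):
        x = np.array([0.1, 0.4, -0.2, 0.3, 0.0])
        result = window_test(x, x.copy(), alpha=0.05)
        assert not result.kept
        assert result.p_value == pytest.approx(0.5, abs=0.01)

    def test_large_constant_shift_kept(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 100)
        result = window_test(base + 10, base, alpha=0.05)
        assert result.kept and result.p_value < 1e-10

    def test_matches_manual_welch_oracle(self):
        window = np.array([0.9, 0.8, 0.85])
        baseline = np.array([0.0, 0.1, -0.1])
        result = window_test(window, baseline, alpha=0.05)
        # Welch statistic and Welch-Satterthwaite df, computed by hand
        va, vb = window.var(ddof=1) / 3, baseline.var(ddof=1) / 3
        t = (window.mean() - baseline.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p = sps.t.sf(t, df)
        assert result.t_statistic == pytest.approx(t, rel=1e-12)
        assert result.p_value == pytest.approx(p, rel=1e-12)

    def test_degenerate_sample_not_kept_with_warning(self):
        with pytest.warns(UserWarning):
            result = window_test(np.array([0.5]), np.array([0.1, 0.2]), 0.05)
        assert not result.kept and result.p_value == 1.0


def _make_windows_and_means(n_windows, size=3):
    windows, log_means = [], {}
    gid = 0
    for w in range(n_windows):
        window = []
        for _ in range(size):
            name = f"g{gid:03d}"
            log_means[name] = float(w + gid * 1e-3)
            window.append(name)
            gid += 1
        windows.append(window)
    return windows, log_means


def _results(flags):
    return [
        WindowTestResult(i + 1, (0.0, 1.0), 3, 1.0, 0.01 if kept else 0.9, kept)
        for i, kept in enumerate(flags)
    ]


class TestSelectThreshold:
    def test_contiguous_run_from_top(self):
        windows, log_means = _make_windows_and_means(6)
        result = select_threshold(_results([False, False, True, True, True]), windows, log_means)
        assert result.retained_gene_ids == {g for w in windows[3:] for g in w}
        assert result.mean_expression_threshold == min(log_means[g] for g in windows[3])
        assert result.isolated_kept_windows == []

    def test_isolated_kept_window_excluded_and_reported(self):
        windows, log_means = _make_windows_and_means(6)
        result = select_threshold(_results([False, True, False, True, True]), windows, log_means)
        assert result.retained_gene_ids == {g for w in windows[4:] for g in w}
        assert result.isolated_kept_windows == [2]

    def test_nothing_kept_gives_sentinel(self):
        windows, log_means = _make_windows_and_means(4)
        result = select_threshold(_results([False, False, False]), windows, log_means)
        assert result.retained_gene_ids == set()
        assert result.mean_expression_threshold == np.inf

    def test_everything_kept_retains_baseline_window(self):
        windows, log_means = _make_windows_and_means(4)
        result = select_threshold(_results([True, True, True]), windows, log_means)
        assert result.retained_gene_ids == {g for w in windows for g in w}
        assert result.mean_expression_threshold == min(log_means[g] for g in windows[0])


class TestFullProcedure:
    @pytest.fixture(scope="class")
    def sim(self):
        config = SimulationConfig(n_genes=1500, seed=4, n_highcv=100)
        matrix, truth = simulate_matrix(config)
        return matrix, truth

    def test_cell_order_invariance(self, sim):
        matrix, _ = sim
        config = ThresholdConfig(window_size=150)
        res1 = run_noise_threshold(matrix, config)
        perm = np.random.default_rng(0).permutation(matrix.n_cells)
        shuffled = ExpressionMatrix(
            list(matrix.gene_ids),
            [matrix.cell_ids[i] for i in perm],
            matrix.values[:, perm],
        )
        res2 = run_noise_threshold(shuffled, config)
        assert res1.retained_gene_ids == res2.retained_gene_ids
        assert res1.mean_expression_threshold == res2.mean_expression_threshold

    def test_retained_set_grows_with_alpha(self, sim):
        matrix, _ = sim
        previous = None
        for alpha in (1e-6, 0.05, 0.5):
            retained = run_noise_threshold(
                matrix, ThresholdConfig(window_size=150, alpha=alpha)
            ).retained_gene_ids
            if previous is not None:
                assert previous <= retained
            previous = retained

    def test_retained_means_dominate_discarded_means(self, sim):
        matrix, _ = sim
        result = run_noise_threshold(matrix, ThresholdConfig(window_size=150))
        stats_means = dict(zip(matrix.gene_ids, matrix.values.mean(axis=1)))
        retained_non_ref = result.retained_gene_ids - result.reference_gene_ids
        windowed = set(filter_zero_genes(matrix, 36).gene_ids) - result.reference_gene_ids
        discarded = windowed - result.retained_gene_ids
        if retained_non_ref and discarded:
            assert min(stats_means[g] for g in retained_non_ref) >= max(
                stats_means[g] for g in discarded
            )

    def test_noise_boundary_recovered_within_a_window(self, sim):
        matrix, truth = sim
        result = run_noise_threshold(matrix, ThresholdConfig(window_size=150))
        spans = [
            w.mean_expr_range[1] - w.mean_expr_range[0]
            for w in result.window_results
            if w.window_index > 0
        ]
        assert (
            abs(result.mean_expression_threshold - truth.true_noise_boundary_mean)
            <= max(spans)
        )

    def test_stronger_technical_noise_raises_threshold(self):
        thresholds = []
        for a in (0.5, 2.0, 8.0):
            recovered = []
            for seed in range(4):
                config = SimulationConfig(n_genes=1500, seed=seed, tech_noise_a=a, n_highcv=100)
                matrix, _ = simulate_matrix(config)
                res = run_noise_threshold(matrix, ThresholdConfig(window_size=150))
                recovered.append(res.mean_expression_threshold)
            thresholds.append(np.mean(recovered))
        rho, _ = sps.spearmanr([0.5, 2.0, 8.0], thresholds)
        assert rho > 0
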