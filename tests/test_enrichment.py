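"""Promoter windows, occupancy counts, hypergeometric preference, degree bins."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cellvar.enrichment import (
    add_bh_fdr,
    binned_degree_vs_cv,
    bivalency_vs_cv,
    count_factors_per_promoter,
    exclusive_preference_test,
    factor_preference_test,
    make_promoters,
    occupancy_vs_cv,
    promoter_class_vs_cv,
)
from cellvar.io import IntervalSet
from cellvar.results import EnrichmentResult


def _annotations(rows):
    df = pd.DataFrame(rows).set_index("gene_id")
    return df


def _stats(cvs, high=None):
    idx = pd.Index([f"g{i:03d}" for i in range(len(cvs))], name="gene_id")
    high = set() if high is None else set(high)
    return pd.DataFrame(
        {
            "mean_fpkm": 1.0,
            "sd_fpkm": np.asarray(cvs, dtype=float),
            "cv": np.asarray(cvs, dtype=float),
            "zero_count": 0,
            "retained": True,
            "high_cv": [g in high for g in idx],
        },
        index=idx,
    )


class TestPromoters:
    def test_symmetric_window_on_both_strands(self):
        ann = _annotations(
            [
                {"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000},
                {"gene_id": "g2", "chrom": "chr1", "strand": "-", "tss": 10_000},
            ]
        )
        p1, p2 = make_promoters(ann, flank=1000)
        assert (p1.start, p1.end) == (9000, 11_000)
        assert (p2.start, p2.end) == (9000, 11_000)  # centred on TSS either strand

    def test_clipped_at_chromosome_start(self):
        ann = _annotations([{"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 500}])
        (p,) = make_promoters(ann, flank=1000)
        assert (p.start, p.end) == (0, 1500)

    def test_gene_without_tss_skipped(self):
        ann = _annotations(
            [
                {"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 5000},
                {"gene_id": "g2", "chrom": "chr1", "strand": "+", "tss": pd.NA},
            ]
        )
        promoters = make_promoters(ann)
        assert [p.gene_id for p in promoters] == ["g1"]


class TestFactorCounting:
    PROMOTERS = _annotations(
        [{"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000}]
    )

    def _count(self, peak_sets):
        return count_factors_per_promoter(make_promoters(self.PROMOTERS), peak_sets)

    def test_overlapping_peak_counts_once(self):
        counts = self._count([IntervalSet("f1", [("chr1", 10_500, 10_600)])])
        assert counts == {"g1": 1}

    def test_touching_peak_does_not_overlap(self):
        counts = self._count([IntervalSet("f1", [("chr1", 11_000, 11_100)])])
        assert counts == {"g1": 0}

    def test_distinct_factors_not_peaks(self):
        two_peaks = IntervalSet("f1", [("chr1", 9100, 9200), ("chr1", 10_500, 10_600)])
        other = IntervalSet("f2", [("chr1", 9100, 9200)])
        assert self._count([two_peaks]) == {"g1": 1}
        assert self._count([two_peaks, other]) == {"g1": 2}

    def test_invariant_to_splitting_a_peak_into_abutting_halves(self):
        whole = IntervalSet("f1", [("chr1", 9100, 9300)])
        split = IntervalSet("f1", [("chr1", 9100, 9200), ("chr1", 9200, 9300)])
        assert self._count([whole]) == self._count([split])


def _enumeration_oracle(n_universe, n_high, n_targets, k):
    """P(overlap >= k) by exhaustive enumeration of all target draws."""
    universe = range(n_universe)
    high = set(range(n_high))
    hits = total = 0
    for draw in itertools.combinations(universe, n_targets):
        total += 1
        hits += len(high.intersection(draw)) >= k
    return hits / total


class TestFactorPreference:
    def test_worked_example_six_over_252(self):
        universe = [f"g{i}" for i in range(10)]
        result = factor_preference_test(universe[:5], universe[1:5], universe)
        # overlap 4 of 5 targets drawn from 10 genes containing 4 High-CV
        assert result.statistic == 4
        assert result.p_value == pytest.approx(6 / 252, abs=1e-12)
        assert result.effect_direction == "enriched"

    def test_targets_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(8)]
        result = factor_preference_test(universe, universe[:3], universe)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universes(self):
        for n_univ in (4, 6, 8):
            genes = [f"g{i}" for i in range(n_univ)]
            for n_high, n_targ in itertools.product(range(n_univ + 1), repeat=2):
                high = genes[:n_high]
                targets = genes[:n_targ]  # maximal overlap layout
                k = min(n_high, n_targ)
                result = factor_preference_test(targets, high, genes)
                assert result.p_value == pytest.approx(
                    _enumeration_oracle(n_univ, n_high, n_targ, k), abs=1e-12
                )

    def test_monotone_in_overlap(self):
        from scipy.stats import hypergeom

        p_values = [float(hypergeom.sf(k - 1, 20, 8, 10)) for k in range(9)]
        assert all(a >= b for a, b in zip(p_values, p_values[1:]))

    def test_subset_precondition(self):
        with pytest.raises(ValueError, match="subset"):
            factor_preference_test({"zz"}, {"g1"}, {"g1", "g2"})

    def test_exclusive_preference_logic(self):
        universe = [f"g{i}" for i in range(40)]
        high, non_high = set(universe[:10]), set(universe[10:])
        targets = set(universe[:9])  # almost perfectly High-CV specific
        res_high, res_non, exclusive = exclusive_preference_test(
            targets, high, non_high, universe
        )
        assert exclusive and res_high.p_value < 1e-6 and res_non.p_value > 0.05


class TestOccupancy:
    def test_planted_anticorrelation_reported_lower_cv(self):
        rng = np.random.default_rng(0)
        cvs = np.concatenate([rng.normal(0.6, 0.05, 60), rng.normal(1.4, 0.05, 60)])
        stats = _stats(cvs)
        counts = {g: (25 if i < 60 else 2) for i, g in enumerate(stats.index)}
        result = occupancy_vs_cv(stats, counts, cut=10)
        assert result.evaluated and result.p_value < 1e-10
        assert result.effect_direction == "lower_cv"  # high occupancy, low CV

    def test_all_genes_at_cut_not_evaluated(self):
        stats = _stats(np.linspace(0.1, 2.0, 80))
        result = occupancy_vs_cv(stats, {g: 10 for g in stats.index}, cut=10)
        assert not result.evaluated
        assert result.extras["n_at_cut"] == 80


class TestDegreeBins:
    def test_mirna_bin_edges(self):
        stats = _stats(np.linspace(0.5, 1.5, 3))
        degrees = dict(zip(stats.index, [3, 77, 150]))
        summary, _ = binned_degree_vs_cv(stats, degrees, (50, 100), min_group=1)
        assert summary["bin"].tolist() == ["1-50", "51-100", ">100"]
        assert summary["n"].tolist() == [1, 1, 1]

    def test_ppi_bin_edges(self):
        stats = _stats(np.linspace(0.5, 1.5, 4))
        degrees = dict(zip(stats.index, [1, 2, 3, 4]))
        summary, tests = binned_degree_vs_cv(stats, degrees, (1, 2, 3), min_group=1)
        assert summary["bin"].tolist() == ["1", "2", "3", ">3"]
        assert summary["n"].tolist() == [1, 1, 1, 1]
        assert len(tests) == 3  # adjacent pairs

    def test_degree_zero_excluded(self):
        stats = _stats(np.linspace(0.5, 1.5, 3))
        degrees = dict(zip(stats.index, [0, 5, 60]))
        summary, _ = binned_degree_vs_cv(stats, degrees, (50, 100), min_group=1)
        assert summary["n"].sum() == 2

    def test_increasing_edges_required(self):
        with pytest.raises(ValueError, match="increasing"):
            binned_degree_vs_cv(_stats([1.0, 1.0]), {}, (50, 50))


class TestBivalency:
    def _annotated_stats(self, rng, n=240, planted=True):
        cvs = rng.gamma(4, 0.2, n)
        labels = np.array(["other"] * n, dtype=object)
        order = np.argsort(cvs)
        if planted:
            labels[order[-80:]] = "bivalent"
            labels[order[:80]] = "active"
        else:
            labels[rng.permutation(n)[:80]] = "bivalent"
            labels[rng.permutation(n)[:80]] = "active"
        high = {f"g{i:03d}" for i in order[-60:]}
        stats = _stats(cvs, high=high)
        ann = pd.DataFrame({"bivalency": labels}, index=stats.index)
        return stats, ann

    def test_planted_bivalency_significant_both_ways(self):
        stats, ann = self._annotated_stats(np.random.default_rng(1))
        t_res, hg_res = bivalency_vs_cv(stats, ann)
        assert t_res.evaluated and t_res.p_value < 1e-6
        assert t_res.effect_direction == "higher_cv"
        assert hg_res.evaluated and hg_res.p_value < 1e-6
        assert hg_res.effect_direction == "enriched"

    def test_single_class_not_evaluated(self):
        stats = _stats(np.linspace(0.1, 2.0, 50))
        ann = pd.DataFrame({"bivalency": ["bivalent"] * 50}, index=stats.index)
        t_res, hg_res = bivalency_vs_cv(stats, ann)
        assert not t_res.evaluated and not hg_res.evaluated


class TestPromoterClass:
    def test_feature_absent_not_evaluated(self):
        stats = _stats(np.linspace(0.1, 2.0, 50))
        ann = pd.DataFrame(index=stats.index)
        assert not promoter_class_vs_cv(stats, ann, "tata").evaluated

    def test_planted_cpg_direction(self):
        rng = np.random.default_rng(2)
        cvs = np.concatenate([rng.normal(0.5, 0.05, 60), rng.normal(1.5, 0.05, 60)])
        stats = _stats(cvs)
        ann = pd.DataFrame(
            {"cpg_island": pd.array([True] * 60 + [False] * 60, dtype="boolean")},
            index=stats.index,
        )
        result = promoter_class_vs_cv(stats, ann, "cpg_island")
        assert result.evaluated and result.p_value < 1e-10
        assert result.effect_direction == "lower_cv"

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            promoter_class_vs_cv(_stats([1.0, 1.0]), pd.DataFrame(), "bivalency")


def test_bh_fdr_attached_to_evaluated_results_only():
    results = [
        EnrichmentResult("a", 1.0, 0.01, 10, 10, "none"),
        EnrichmentResult("b", 1.0, 0.04, 10, 10, "none"),
        EnrichmentResult.not_evaluated("c"),
    ]
    out = add_bh_fdr(results)
    assert out[0].extras["q_value_bh"] == pytest.approx(0.02)
    assert out[1].extras["q_value_bh"] == pytest.approx(0.04)
    assert "q_value_bh" not in out[2].extras
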