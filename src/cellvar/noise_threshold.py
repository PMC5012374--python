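"""Correlation-window procedure separating biological from technical variation.

Lowly expressed genes in single-cell FPKM matrices are dominated by technical
noise (amplification bias, dropout).  The procedure exploits the fact that
well-measured genes co-vary with the most highly expressed genes through the
shared cell state, while noise-dominated genes do not:

1. discard genes with too many zero values;
2. take genes above a high FPKM floor in *every* cell as a confident
   reference set;
3. sort the remaining genes by mean expression and cut them into windows of
   ``window_size`` genes (the remainder is pooled into the lowest window);
4. correlate every window gene with every reference gene across cells;
5. Welch-t-test each window's correlation distribution against the lowest
   (noise) window, one-sided for a right shift;
6. keep the maximal contiguous run of significant windows ending at the
   highest-mean window; the expression threshold is the low edge of that run.

Retention is window-level: the procedure reports a single mean-expression
threshold, and all genes at or above it (plus the reference genes, biological
by construction) are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "WindowTestResult",
    "ThresholdResult",
    "filter_zero_genes",
    "select_reference_genes",
    "bin_genes_by_mean",
    "window_correlation_distribution",
    "test_window_against_baseline",
    "select_threshold",
    "run_noise_threshold",
]


@dataclass
class ThresholdConfig:
    """Tunables of the noise-threshold procedure.

    ``max_zero_cells=None`` defaults to 90% of the cell count, matching the
    spirit of a 35-of-39-cells zero cutoff.  ``corr_on_log`` switches the
    pairwise correlations from raw FPKM (the default) to log(FPKM + offset).
    ``bonferroni`` divides alpha by the number of tested windows.
    """

    max_zero_cells: int | None = None
    ref_min_fpkm: float = 150.0
    window_size: int = 1000
    alpha: float = 0.05
    log_offset: float = 1.0
    corr_on_log: bool = False
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be > 0")


@dataclass
class WindowTestResult:
    """Per-window one-sided Welch test against the lowest (noise) window."""

    window_index: int  # 0 = lowest mean expression (the baseline itself)
    mean_expr_range: tuple[float, float]  # log(FPKM + offset) of window gene means
    n_genes: int
    t_statistic: float
    p_value: float
    kept: bool
    n_dropped_pairs: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mean_expr_range
        if lo > hi:
            raise ValueError("mean_expr_range must be ordered")
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ThresholdResult:
    reference_gene_ids: set[str]
    retained_gene_ids: set[str]
    mean_expression_threshold: float  # log(FPKM + offset); +inf if nothing kept
    window_results: list[WindowTestResult]
    isolated_kept_windows: list[int] = field(default_factory=list)
    n_genes_input: int = 0
    n_genes_after_zero_filter: int = 0


def filter_zero_genes(matrix: ExpressionMatrix, max_zero_cells: int) -> ExpressionMatrix:
    """Drop genes with ``max_zero_cells`` *or more* zero values."""
    if max_zero_cells > matrix.n_cells:
        raise ValueError("max_zero_cells exceeds the number of cells")
    keep = matrix.zero_counts() < max_zero_cells
    if not keep.any():
        warnings.warn("zero filter removed every gene", stacklevel=2)
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    logger.info("zero filter: %d of %d genes retained", len(kept_ids), matrix.n_genes)
    return ExpressionMatrix(kept_ids, list(matrix.cell_ids), matrix.values[keep])


def select_reference_genes(matrix: ExpressionMatrix, min_fpkm: float) -> set[str]:
    """Genes strictly above ``min_fpkm`` in every single cell."""
    ok = matrix.values.min(axis=1) > min_fpkm
    refs = {g for g, k in zip(matrix.gene_ids, ok) if k}
    if not refs:
        raise ValueError(
            f"no gene exceeds {min_fpkm} FPKM in every cell; "
            "lower ref_min_fpkm to obtain a reference set"
        )
    return refs


def bin_genes_by_mean(
    matrix: ExpressionMatrix, window_size: int, exclude: set[str] = frozenset()
) -> list[list[str]]:
    """Sort non-excluded genes by mean FPKM and cut into windows, low to high.

    The remainder (fewer than ``window_size`` genes) is merged into the lowest
    window, which therefore may exceed ``window_size``.  Mean ties are broken
    by gene id, so the windows are invariant to input row order.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    means = matrix.gene_means()
    pool = sorted(
        ((m, g) for g, m in zip(matrix.gene_ids, means) if g not in exclude),
        key=lambda t: (t[0], t[1]),
    )
    n = len(pool)
    if n < 2 * window_size:
        raise ValueError(
            f"need at least {2 * window_size} genes (one baseline plus one test "
            f"window); got {n}"
        )
    n_windows = n // window_size
    remainder = n - n_windows * window_size
    sizes = [window_size + remainder] + [window_size] * (n_windows - 1)
    windows, start = [], 0
    for size in sizes:
        windows.append([g for _, g in pool[start : start + size]])
        start += size
    return windows


def _corr_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardise rows for correlation; returns (z, non_constant_mask)."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    ok = norms > 0
    z = np.zeros_like(centred)
    z[ok] = centred[ok] / norms[ok, None]
    return z, ok


def window_correlation_distribution(
    matrix: ExpressionMatrix,
    window_genes: list[str],
    reference_genes,
    on_log: bool = False,
    log_offset: float = 1.0,
) -> tuple[np.ndarray, int]:
    """All window-gene x reference-gene Pearson correlations across cells.

    Pairs involving a constant vector are undefined and dropped; the count of
    dropped pairs is returned alongside the correlations.
    """
    refs = sorted(reference_genes)
    if len(window_genes) < 2 or len(refs) < 2:
        raise ValueError("need at least 2 window genes and 2 reference genes")
    w = matrix.subset_genes(window_genes).values
    r = matrix.subset_genes(refs).values
    if on_log:
        w = np.log(w + log_offset)
        r = np.log(r + log_offset)
    zw, ok_w = _corr_rows(w)
    zr, ok_r = _corr_rows(r)
    corrs = (zw[ok_w] @ zr[ok_r].T).ravel()
    np.clip(corrs, -1.0, 1.0, out=corrs)
    n_dropped = len(window_genes) * len(refs) - corrs.size
    if n_dropped:
        logger.info("dropped %d undefined correlation pairs (constant vectors)", n_dropped)
    return corrs, n_dropped


def test_window_against_baseline(
    window_corrs: np.ndarray,
    baseline_corrs: np.ndarray,
    alpha: float,
    *,
    window_index: int = -1,
    mean_expr_range: tuple[float, float] = (np.nan, np.nan),
    n_genes: int = 0,
    n_dropped_pairs: int = 0,
) -> WindowTestResult:
    """One-sided Welch t-test: window correlations shifted right of baseline."""
    window_corrs = np.asarray(window_corrs, dtype=float)
    baseline_corrs = np.asarray(baseline_corrs, dtype=float)
    if window_corrs.size < 2 or baseline_corrs.size < 2:
        warnings.warn(
            f"window {window_index}: fewer than 2 correlation values on one side; "
            "treating as not kept",
            stacklevel=2,
        )
        return WindowTestResult(
            window_index, mean_expr_range, n_genes, np.nan, 1.0, False, n_dropped_pairs
        )
    t, p = stats.ttest_ind(window_corrs, baseline_corrs, equal_var=False, alternative="greater")
    t, p = float(t), float(p)
    if np.isnan(p):  # both samples constant (e.g. identical correlation values)
        t, p = 0.0, 1.0
    return WindowTestResult(
        window_index, mean_expr_range, n_genes, t, p, p < alpha, n_dropped_pairs
    )


def select_threshold(
    window_results: list[WindowTestResult],
    windows: list[list[str]],
    log_means: dict[str, float],
) -> ThresholdResult:
    """Turn per-window keep flags into a threshold and a retained gene set.

    ``window_results`` covers windows 1..W (ordered low to high mean);
    ``windows`` additionally includes the untested baseline window at index 0.
    The retained set is the maximal contiguous run of kept windows ending at
    the highest window; isolated kept windows below the run are logged, not
    retained.  When every tested window is kept, no noise regime was detected
    anywhere, so the baseline window is retained as well and the threshold is
    its low edge.  When no window is kept the threshold is +inf.
    """
    if len(window_results) != len(windows) - 1:
        raise ValueError("expected one test result per non-baseline window")
    kept_flags = [r.kept for r in window_results]
    run_start = None  # index into `windows`
    for i in range(len(kept_flags) - 1, -1, -1):
        if kept_flags[i]:
            run_start = i + 1
        else:
            break
    isolated = [
        r.window_index
        for r, flag in zip(window_results, kept_flags)
        if flag and (run_start is None or r.window_index < run_start)
    ]
    if isolated:
        logger.info("isolated significant windows excluded from retention: %s", isolated)

    if run_start is None:
        return ThresholdResult(set(), set(), float("inf"), list(window_results), isolated)
    if run_start == 1:  # every tested window kept: no noise floor detected
        run_start = 0
    retained = {g for w in windows[run_start:] for g in w}
    threshold = min(log_means[g] for g in windows[run_start])
    return ThresholdResult(set(), retained, threshold, list(window_results), isolated)


def run_noise_threshold(matrix: ExpressionMatrix, config: ThresholdConfig) -> ThresholdResult:
    """Run the full procedure on a matrix; deterministic, cell-order invariant."""
    max_zero = (
        config.max_zero_cells
        if config.max_zero_cells is not None
        else max(1, int(round(0.9 * matrix.n_cells)))
    )
    filtered = filter_zero_genes(matrix, max_zero)
    refs = select_reference_genes(filtered, config.ref_min_fpkm)
    windows = bin_genes_by_mean(filtered, config.window_size, exclude=refs)
    log_means = dict(
        zip(filtered.gene_ids, np.log(filtered.gene_means() + config.log_offset))
    )

    baseline, _ = window_correlation_distribution(
        filtered, windows[0], refs, config.corr_on_log, config.log_offset
    )
    alpha = config.alpha / (len(windows) - 1) if config.bonferroni else config.alpha
    results = []
    for i, window in enumerate(windows[1:], start=1):
        corrs, n_dropped = window_correlation_distribution(
            filtered, window, refs, config.corr_on_log, config.log_offset
        )
        span = [log_means[g] for g in window]
        results.append(
            test_window_against_baseline(
                corrs,
                baseline,
                alpha,
                window_index=i,
                mean_expr_range=(min(span), max(span)),
                n_genes=len(window),
                n_dropped_pairs=n_dropped,
            )
        )
    base_span = [log_means[g] for g in windows[0]]
    base_result = WindowTestResult(
        0, (min(base_span), max(base_span)), len(windows[0]), np.nan, np.nan, False
    )

    result = select_threshold(results, windows, log_means)
    result.window_results = [base_result] + result.window_results
    result.reference_gene_ids = refs
    result.retained_gene_ids |= refs  # references are biological by construction
    result.n_genes_input = matrix.n_genes
    result.n_genes_after_zero_filter = filtered.n_genes
    logger.info(
        "noise threshold %.3f log(FPKM+%g); %d genes retained (%d references)",
        result.mean_expression_threshold,
        config.log_offset,
        len(result.retained_gene_ids),
        len(refs),
    )
    return result
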