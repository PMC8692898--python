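"""Expression-side computations: QC filters, the rank-based p-EMT signature
score, marker-gene selection, and group-fraction tests.

The container is an :class:`anndata.AnnData` with nonnegative RPKM-like
values in ``X``, cells in ``obs`` and genes in ``var``.

The p-EMT score of a cell is the mean within-cell expression rank of the
signature genes (ties averaged), normalized by the number of ranked genes so
it lies in (0, 1]: a cell whose signature genes sit at the top of its own
expression distribution scores near 1. Being rank-based, the score is
invariant to any strictly increasing per-cell transformation of expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

_EPS = 1e-9  # pseudocount protecting fold changes against a zero-mean "rest"


@dataclass
class SignatureScore:
    """Per-cell normalized mean-rank signature scores."""

    scores: np.ndarray  # (n_cells,) float in (0, 1]
    cell_ids: np.ndarray
    signature: list
    n_signature_used: int

    def __post_init__(self) -> None:
        if len(self.scores) and not (
            np.all(self.scores >= 0.0) and np.all(self.scores <= 1.0 + 1e-12)
        ):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class TestResult:
    """Outcome of a two-group comparison, including which test actually ran."""

    method: str  # wilcoxon_rank_sum | mann_whitney | t_unpaired | t_paired | wilcoxon_signed_rank
    statistic: float
    p: float
    n1: int
    n2: int
    normality_gate: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=np.float64)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    adata: ad.AnnData, min_genes_per_cell: int = 400, min_cells_per_gene: int = 4
) -> ad.AnnData:
    """Drop sparse cells, then sparse genes, in a single pass.

    A gene is "expressed" in a cell when its value is > 0. Cells with fewer
    than ``min_genes_per_cell`` expressed genes are removed first; genes
    expressed in fewer than ``min_cells_per_gene`` of the *remaining* cells
    are removed second. The order (cells, then genes, no iteration to a
    fixed point) is recorded in ``uns["qc_filter"]``.
    """
    X = _dense(adata.X)
    if np.any(X < 0):
        raise ValueError("expression values must be nonnegative")
    genes_per_cell = (X > 0).sum(axis=1)
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("QC filter removed every cell")
    X2 = X[keep_cells]
    cells_per_gene = (X2 > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = adata[keep_cells, keep_genes].copy()
    out.uns["qc_filter"] = {
        "order": "cells_then_genes",
        "min_genes_per_cell": min_genes_per_cell,
        "min_cells_per_gene": min_cells_per_gene,
        "n_cells_removed": int((~keep_cells).sum()),
        "n_genes_removed": int((~keep_genes).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# p-EMT signature score
# ---------------------------------------------------------------------------


def pemt_score(
    adata: ad.AnnData, signature: Sequence[str], orientation: str = "per_cell"
) -> SignatureScore:
    """Normalized mean-rank signature score per cell.

    ``per_cell`` (default): within each cell, rank all genes in the matrix by
    expression (ascending, average ranks for ties), average the ranks of the
    signature genes present, and divide by the number of ranked genes.
    ``per_gene`` is the alternative reading — rank cells within each gene —
    normalized by the number of cells.

    Signature genes missing from the matrix are excluded;
    ``n_signature_used`` records how many were found.
    """
    sig = list(dict.fromkeys(signature))
    present = [g for g in sig if g in adata.var_names]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    X = _dense(adata.X)
    n_cells, n_genes = X.shape
    col_idx = [adata.var_names.get_loc(g) for g in present]
    if orientation == "per_cell":
        ranks = stats.rankdata(X, axis=1)  # (cells, genes), ascending
        scores = ranks[:, col_idx].mean(axis=1) / n_genes
    elif orientation == "per_gene":
        ranks = stats.rankdata(X, axis=0)
        scores = ranks[:, col_idx].mean(axis=1) / n_cells
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return SignatureScore(
        scores=np.asarray(scores, dtype=float),
        cell_ids=np.asarray(adata.obs_names),
        signature=sig,
        n_signature_used=len(present),
    )


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U of the first sample).

    Exact when both groups are small and tie-free; otherwise the normal
    approximation with tie correction (no continuity correction, so that
    exchangeable groups give p = 1 exactly).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(x), len(y)) <= 50 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_scores(
    scores: SignatureScore | np.ndarray, groups: Sequence[str]
) -> TestResult:
    """Two-sided Wilcoxon rank-sum comparison of per-cell scores between two groups."""
    vals = scores.scores if isinstance(scores, SignatureScore) else np.asarray(scores, float)
    groups = np.asarray(groups)
    if len(groups) != len(vals):
        raise ValueError("groups must align with scores")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = vals[groups == levels[0]]
    b = vals[groups == levels[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs at least 3 cells")
    stat, p = _rank_sum_test(a, b)
    return TestResult(
        method="wilcoxon_rank_sum", statistic=stat, p=p, n1=len(a), n2=len(b)
    )


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------


def find_markers(
    adata: ad.AnnData,
    clusters: Sequence[str],
    target: str,
    p_adj_max: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Marker genes of ``target`` versus all other clusters.

    Per gene: two-sided Wilcoxon rank-sum of target cells against the rest,
    Bonferroni correction over the genes actually tested (those with any
    variance across cells). Kept genes must satisfy both
    ``p_adj < p_adj_max`` and raw-mean fold change
    ``mean(target) / mean(rest) > min_fold`` (a tiny pseudocount guards a
    zero-mean rest). Result is sorted by fold change, descending.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != adata.n_obs:
        raise ValueError("clusters must align with cells")
    if len(pd.unique(clusters)) < 2:
        raise ValueError("need at least two clusters")
    in_target = clusters == target
    if in_target.sum() < 3:
        raise ValueError("target cluster needs at least 3 cells")
    X = _dense(adata.X)
    xt, xr = X[in_target], X[~in_target]
    variable = X.std(axis=0) > 0
    n_tested = int(variable.sum())
    rows = []
    for j in np.flatnonzero(variable):
        stat, p = _rank_sum_test(xt[:, j], xr[:, j])
        p_adj = min(p * n_tested, 1.0)
        fold = xt[:, j].mean() / (xr[:, j].mean() + _EPS)
        if p_adj < p_adj_max and fold > min_fold:
            rows.append({"gene": adata.var_names[j], "p_adj": p_adj, "fold_change": fold})
    out = pd.DataFrame(rows, columns=["gene", "p_adj", "fold_change"])
    return out.sort_values("fold_change", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# group-fraction tests with a normality gate
# ---------------------------------------------------------------------------


def compare_fractions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
    alpha_gate: float = 0.05,
) -> TestResult:
    """Compare per-sample fractions between two groups, gated on normality.

    Unpaired: Shapiro-Wilk on each group plus a two-sided F-ratio check of
    variance equality, all at ``alpha_gate``; every check passing selects
    the unpaired t test, otherwise the Mann-Whitney test. Paired:
    Shapiro-Wilk on the within-pair differences selects the paired t test,
    otherwise (or when the differences are degenerate) the Wilcoxon
    signed-rank test. The gate outcome is recorded on the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        if len(a) < 3:
            raise ValueError("need at least 3 pairs")
        diffs = a - b
        if np.ptp(diffs) == 0 or np.all(diffs == 0):
            if np.all(diffs == 0):
                return TestResult(
                    method="wilcoxon_signed_rank",
                    statistic=0.0,
                    p=1.0,
                    n1=len(a),
                    n2=len(b),
                    normality_gate="degenerate_differences",
                )
            res = stats.wilcoxon(a, b, alternative="two-sided")
            return TestResult(
                method="wilcoxon_signed_rank",
                statistic=float(res.statistic),
                p=float(res.pvalue),
                n1=len(a),
                n2=len(b),
                normality_gate="degenerate_differences",
            )
        sw_p = stats.shapiro(diffs).pvalue
        if sw_p > alpha_gate:
            res = stats.ttest_rel(a, b)
            return TestResult(
                method="t_paired",
                statistic=float(res.statistic),
                p=float(res.pvalue),
                n1=len(a),
                n2=len(b),
                normality_gate=f"normal (Shapiro p={sw_p:.3g})",
            )
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return TestResult(
            method="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            n1=len(a),
            n2=len(b),
            normality_gate=f"non-normal (Shapiro p={sw_p:.3g})",
        )

    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 samples per group")
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    if degenerate:
        stat, p = _rank_sum_test(a, b)
        return TestResult(
            method="mann_whitney",
            statistic=stat,
            p=p,
            n1=len(a),
            n2=len(b),
            normality_gate="degenerate_variance",
        )
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    va, vb = a.var(ddof=1), b.var(ddof=1)
    f = max(va, vb) / min(va, vb)
    dfn = (len(a) if va >= vb else len(b)) - 1
    dfd = (len(b) if va >= vb else len(a)) - 1
    f_p = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    if sw_a > alpha_gate and sw_b > alpha_gate and f_p > alpha_gate:
        res = stats.ttest_ind(a, b, equal_var=True)
        return TestResult(
            method="t_unpaired",
            statistic=float(res.statistic),
            p=float(res.pvalue),
            n1=len(a),
            n2=len(b),
            normality_gate=f"normal (Shapiro p={min(sw_a, sw_b):.3g}, F p={f_p:.3g})",
        )
    stat, p = _rank_sum_test(a, b)
    return TestResult(
        method="mann_whitney",
        statistic=stat,
        p=p,
        n1=len(a),
        n2=len(b),
        normality_gate=f"non-normal or unequal SD (Shapiro p={min(sw_a, sw_b):.3g}, F p={f_p:.3g})",
    )
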