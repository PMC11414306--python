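"""Expression preparation: CPM normalisation, expression filter, three-contrast
differential expression, and top-fraction gene selection.

The differential-expression model is an ordinary least-squares fit on
log2(CPM + 0.5) with RFI group, breed and diet as additive two-level factors,
so testing one contrast always adjusts for the other two. P-values come from
the coefficient t-statistics and are Benjamini-Hochberg adjusted within each
contrast. The per-contrast gene list for the network is the top 5% of
expressed genes by adjusted p-value, with floor(fraction * n) genes selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

CONTRASTS = ("rfi", "breed", "diet")


@dataclass
class CPMMatrix:
    """Counts-per-million values (genes x samples) plus the library sizes."""

    values: pd.DataFrame
    library_sizes: pd.Series


@dataclass
class ContrastResult:
    """Per-gene statistics for one contrast over the expressed genes.

    table columns: log2fc (between-level difference on the log2 CPM scale),
    stat (coefficient t), pvalue, padj (BH within contrast).
    """

    contrast: str
    table: pd.DataFrame
    expressed_gene_count: int


def compute_cpm(counts: pd.DataFrame) -> CPMMatrix:
    """counts / library size * 1e6, per sample."""
    libsizes = counts.sum(axis=0)
    zero = libsizes[libsizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return CPMMatrix(values=counts / libsizes * 1e6, library_sizes=libsizes.astype(float))


def filter_expressed(cpm: CPMMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5) -> pd.Index:
    """Genes with >= min_cpm CPM in at least ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_samples = cpm.values.shape[1]
    if cpm.values.empty:
        warnings.warn("empty CPM matrix; no genes retained")
        return pd.Index([])
    need = math.ceil(min_fraction * n_samples)
    keep = (cpm.values >= min_cpm).sum(axis=1) >= need
    return cpm.values.index[keep]


def fit_contrasts(
    cpm_values: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 0.5
) -> dict[str, ContrastResult]:
    """OLS on log2(CPM + pseudocount) with additive rfi/breed/diet factors.

    design must carry rfi_group, breed and diet columns indexed by sample, each
    with exactly two levels over the fitted samples; levels are coded +1/-1
    (first sorted level positive) and the reported log2fc is the between-level
    difference, i.e. twice the coefficient. Genes that are constant across
    samples get stat 0 and p 1.
    """
    cols = {"rfi": "rfi_group", "breed": "breed", "diet": "diet"}
    design = design.loc[cpm_values.columns]
    coded = {}
    for contrast, col in cols.items():
        levels = sorted(design[col].unique())
        if len(levels) != 2:
            raise ValueError(f"factor {col!r} must have exactly 2 levels, got {levels}")
        coded[contrast] = np.where(design[col] == levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones(len(design))] + [coded[c] for c in CONTRASTS])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [
            (a, b)
            for i, a in enumerate(CONTRASTS)
            for b in CONTRASTS[i + 1 :]
            if abs(np.corrcoef(coded[a], coded[b])[0, 1]) > 1 - 1e-10
        ]
        raise ValueError(f"confounded design; aliased factors: {aliased or 'with intercept'}")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} samples to fit the model, got {n}")
    Y = np.log2(cpm_values.to_numpy(dtype=float) + pseudocount)  # genes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x p
    resid = Y - beta @ X.T
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    results = {}
    for j, contrast in enumerate(CONTRASTS, start=1):
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[:, j] / se
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: constant gene, no effect
        pvals = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(t), df))
        padj = multipletests(pvals, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"log2fc": 2.0 * beta[:, j], "stat": t, "pvalue": pvals, "padj": padj},
            index=cpm_values.index,
        )
        results[contrast] = ContrastResult(contrast, table, expressed_gene_count=len(table))
    return results


def select_top_fraction(result: ContrastResult, fraction: float = 0.05) -> list[str]:
    """The floor(fraction * n) genes with smallest adjusted p.

    Total order: adjusted p, then raw p, then gene id — so the cut is
    deterministic under ties.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = math.floor(fraction * result.expressed_gene_count)
    ordered = (
        result.table.assign(_gene=result.table.index)
        .sort_values(["padj", "pvalue", "_gene"], kind="mergesort")
        .drop(columns="_gene")
    )
    return list(ordered.index[:k])
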