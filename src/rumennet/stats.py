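"""Downstream statistics: stepwise variance attribution, the phenotype-microbe
correlation table, and hierarchical clustering of phenotype/taxa profiles.

The stepwise analysis is pure greedy forward selection on R^2: at every step
the candidate taxon that maximises the cumulative R^2 of an OLS fit (with
intercept) enters the model, until a target R^2 (default 90%) is reached, no
candidate improves R^2 beyond a tolerance, or candidates/sample degrees of
freedom run out. Clustering is agglomerative on the 1 - r correlation
distance with a deterministic leaf order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform


@dataclass
class RegressionPath:
    """Ordered record of forward selection for one response phenotype."""

    response: str
    steps: list[tuple[str, float, float]]  # (taxon, step R^2 gain, cumulative R^2)
    stopping_reason: str  # target_reached | no_candidates | no_improvement

    @property
    def selected(self) -> list[str]:
        return [s[0] for s in self.steps]

    @property
    def cumulative_r2(self) -> float:
        return self.steps[-1][2] if self.steps else 0.0


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of OLS with intercept."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def stepwise_r2(
    response: pd.Series,
    candidates: pd.DataFrame,
    target_r2: float = 0.90,
    tol: float = 1e-6,
) -> RegressionPath:
    """Greedy forward selection of taxa explaining a phenotype's variance.

    `candidates` holds taxa profiles as rows over the same samples as
    `response`. Ties in R^2 break by candidate label, so the path is invariant
    to candidate ordering. Selection also stops before the OLS would saturate
    (predictors + intercept must stay below the sample count).
    """
    y = response.to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("response is constant; R^2 undefined")
    X_all = candidates.loc[:, response.index].to_numpy(dtype=float)
    labels = list(candidates.index)
    n = len(y)
    chosen: list[int] = []
    steps: list[tuple[str, float, float]] = []
    current = 0.0
    reason = "no_candidates"
    while True:
        if len(chosen) == len(labels):
            reason = "no_candidates"
            break
        if len(chosen) + 2 >= n:  # next fit would leave no residual df
            reason = "no_candidates"
            break
        best: tuple[float, str, int] | None = None
        for j, lab in enumerate(labels):
            if j in chosen:
                continue
            r2 = _r2(y, X_all[[*chosen, j]].T)
            if best is None or r2 > best[0] + 1e-15 or (abs(r2 - best[0]) <= 1e-15 and lab < best[1]):
                best = (r2, lab, j)
        assert best is not None
        r2, lab, j = best
        if r2 - current <= tol:
            reason = "no_improvement"
            break
        chosen.append(j)
        steps.append((lab, r2 - current, r2))
        current = r2
        if current >= target_r2:
            reason = "target_reached"
            break
    return RegressionPath(response=str(response.name), steps=steps, stopping_reason=reason)


def correlation_table(
    phenotypes: pd.DataFrame, taxa: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r, two-sided t-test p, and the p < alpha flag, per pair.

    `phenotypes` is phenotypes x samples, `taxa` is taxa x samples (shared
    columns). Constant taxa yield NaN cells (flagged False).
    """
    n = phenotypes.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples")
    taxa = taxa.loc[:, phenotypes.columns]
    r = pd.DataFrame(index=phenotypes.index, columns=taxa.index, dtype=float)
    p = r.copy()
    for phen in phenotypes.index:
        y = phenotypes.loc[phen].to_numpy(dtype=float)
        for t in taxa.index:
            x = taxa.loc[t].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue  # leave NaN
            rv = float(np.corrcoef(y, x)[0, 1])
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                tstat = rv * np.sqrt(n - 2) / np.sqrt(1 - rv * rv)
                pv = float(2 * sps.t.sf(abs(tstat), n - 2))
            r.loc[phen, t] = rv
            p.loc[phen, t] = pv
    sig = (p < alpha).fillna(False)
    return r, p, sig


@dataclass
class ClusterOrdering:
    """Result of agglomerative clustering on the 1 - r distance."""

    leaf_order: list[str]
    merges: np.ndarray  # scipy linkage matrix over the kept rows
    labels: list[str]  # row labels in linkage input order
    distance: str = "1 - r"
    linkage: str = "average"


def _canonical_leaf_order(Z: np.ndarray, labels: list[str]) -> list[str]:
    """Deterministic dendrogram flattening: smaller subtree first, ties by the
    lexicographically smallest label in the subtree."""
    n = len(labels)

    def walk(node: int) -> tuple[list[int], str]:
        if node < n:
            return [node], labels[node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lo, lmin = walk(left)
        ro, rmin = walk(right)
        if (len(lo), lmin) <= (len(ro), rmin):
            return lo + ro, min(lmin, rmin)
        return ro + lo, min(lmin, rmin)

    order, _ = walk(2 * n - 2) if n > 1 else ([0], labels[0])
    return [labels[i] for i in order]


def hierarchical_cluster(
    profiles: pd.DataFrame, linkage: str = "average"
) -> ClusterOrdering:
    """Cluster profile rows on the 1 - Pearson-r distance.

    Constant rows are dropped with a warning (their correlation is undefined);
    fewer than 2 usable rows is an error. Leaf order is canonicalised so the
    result does not depend on the input row order beyond dendrogram
    reflections.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    X = profiles.to_numpy(dtype=float)
    const = profiles.index[X.std(axis=1) == 0].tolist()
    if const:
        warnings.warn(f"dropping constant row(s) before clustering: {const}")
        profiles = profiles.drop(index=const)
        X = profiles.to_numpy(dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 non-constant rows to cluster")
    labels = list(profiles.index)
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # symmetrise against float jitter
    Z = sch.linkage(squareform(D, checks=False), method=linkage)
    return ClusterOrdering(
        leaf_order=_canonical_leaf_order(Z, labels),
        merges=Z,
        labels=labels,
        linkage=linkage,
    )
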