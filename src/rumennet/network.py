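"""Typed node assembly, correlation, and the PCIT edge filter.

PCIT (partial correlation and information theory) examines every trio of
nodes (x, y, z). For the trio it computes the three first-order partial
correlations

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

and the information-theoretic tolerance eps = mean of the partial/direct
ratios (ratios whose direct correlation is below a small guard delta are left
out of the average; if all three are excluded eps = 1). The edge (x, y) is
eliminated if, in at least one trio, |r_xy| <= |eps * r_xz| and
|r_xy| <= |eps * r_yz| — i.e. the direct association is dominated by the two
indirect routes. Surviving edges keep their correlation and its sign; a
per-edge correlation t-test then applies the printed significance threshold.

Two implementations of the trio loop are provided: a plain O(n^3) reference
(`method="naive"`) and a vectorised pass over conditioning nodes
(`method="fast"`); they execute the same arithmetic and their edge sets are
compared in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

NODE_TYPES = ("gene", "microbe", "vfa", "phenotype")
DEFAULT_PHENOTYPES = ("DMI", "RFI", "ADG")


# ---------------------------------------------------------------------------
# Node table
# ---------------------------------------------------------------------------


def assemble_nodes(
    deg_lists: Mapping[str, Sequence[str]],
    taxa: pd.DataFrame | None = None,
    vfa_names: Sequence[str] = (),
    phenotype_names: Sequence[str] = DEFAULT_PHENOTYPES,
) -> pd.DataFrame:
    """Build the typed node registry for the network.

    Gene nodes are the union of the per-contrast top lists, each recorded once
    with the set of contrasts that selected it (its provenance). Microbe nodes
    come from the taxonomy frame (index = taxon id, columns rank and lineage),
    then VFA and phenotype nodes are appended. Returns a frame indexed by
    node_id with columns node_type, contrasts (';'-joined), rank, lineage.
    """
    provenance: dict[str, list[str]] = {}
    for contrast, genes in deg_lists.items():
        for g in genes:
            provenance.setdefault(g, []).append(contrast)
    listed = sum(len(g) for g in deg_lists.values())
    if listed != len(provenance):
        warnings.warn(
            f"{listed} listed genes collapse to {len(provenance)} unique gene nodes "
            "(multi-contrast membership)"
        )
    rows = [
        {"node_id": g, "node_type": "gene", "contrasts": ";".join(sorted(cs)), "rank": "", "lineage": ""}
        for g, cs in provenance.items()
    ]
    if taxa is not None:
        for t in taxa.index:
            rows.append(
                {
                    "node_id": t,
                    "node_type": "microbe",
                    "contrasts": "",
                    "rank": str(taxa.loc[t, "rank"]) if "rank" in taxa else "",
                    "lineage": str(taxa.loc[t, "lineage"]) if "lineage" in taxa else "",
                }
            )
    for v in vfa_names:
        rows.append({"node_id": v, "node_type": "vfa", "contrasts": "", "rank": "", "lineage": ""})
    for p in phenotype_names:
        rows.append({"node_id": p, "node_type": "phenotype", "contrasts": "", "rank": "", "lineage": ""})
    table = pd.DataFrame(rows).set_index("node_id")
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"node id collision across types: {sorted(set(dup))}")
    return table


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pairwise product-moment correlations over aligned samples."""

    values: pd.DataFrame
    n_samples: int
    constant_nodes: list[str] = field(default_factory=list)


def compute_correlations(profiles: pd.DataFrame) -> CorrelationMatrix:
    """Correlate every pair of node profiles (rows) over the samples (columns).

    Needs at least 4 samples (first-order partials lose 3 degrees of freedom).
    Constant profiles are flagged and their correlations left undefined (NaN);
    drop them (see `drop_constant_nodes`) before running PCIT.
    """
    n = profiles.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 aligned samples, got {n}")
    X = profiles.to_numpy(dtype=float)
    const = profiles.index[X.std(axis=1) == 0].tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    if const:
        idx = [profiles.index.get_loc(c) for c in const]
        R[idx, :] = np.nan
        R[:, idx] = np.nan
    return CorrelationMatrix(
        values=pd.DataFrame(R, index=profiles.index, columns=profiles.index),
        n_samples=n,
        constant_nodes=const,
    )


def drop_constant_nodes(corr: CorrelationMatrix) -> CorrelationMatrix:
    """Remove flagged constant-profile nodes (with a warning) ahead of PCIT."""
    if not corr.constant_nodes:
        return corr
    warnings.warn(f"dropping constant-profile node(s): {corr.constant_nodes}")
    keep = [i for i in corr.values.index if i not in set(corr.constant_nodes)]
    return CorrelationMatrix(corr.values.loc[keep, keep], corr.n_samples, [])


# ---------------------------------------------------------------------------
# Edge set
# ---------------------------------------------------------------------------


@dataclass
class EdgeSet:
    """Weighted signed edges; one row per unordered node pair (a < b)."""

    df: pd.DataFrame  # columns: node_a, node_b, r, sign [, p, significant]

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.df["node_a"], self.df["node_b"]))

    def neighbours(self, node: str) -> list[str]:
        a = self.df.loc[self.df["node_b"] == node, "node_a"]
        b = self.df.loc[self.df["node_a"] == node, "node_b"]
        return sorted(set(a) | set(b))


def _edges_from_keep(R: np.ndarray, names: Sequence[str], keep: np.ndarray) -> EdgeSet:
    ia, ib = np.where(np.triu(keep, k=1))
    order = np.lexsort((ib, ia))
    ia, ib = ia[order], ib[order]
    r = R[ia, ib]
    df = pd.DataFrame(
        {
            "node_a": [names[i] for i in ia],
            "node_b": [names[i] for i in ib],
            "r": r,
            "sign": np.where(r >= 0, "+", "-"),
        }
    )
    return EdgeSet(df)


# ---------------------------------------------------------------------------
# PCIT trio rule
# ---------------------------------------------------------------------------


def trio_tolerance(rxy: float, rxz: float, ryz: float, delta: float = 1e-8) -> float:
    """eps for one trio: mean partial/direct ratio with a small-direct guard."""
    dxy = math.sqrt((1.0 - rxz * rxz) * (1.0 - ryz * ryz))
    dxz = math.sqrt((1.0 - rxy * rxy) * (1.0 - ryz * ryz))
    dyz = math.sqrt((1.0 - rxy * rxy) * (1.0 - rxz * rxz))
    pxy = (rxy - rxz * ryz) / dxy if dxy > 0 else 0.0
    pxz = (rxz - rxy * ryz) / dxz if dxz > 0 else 0.0
    pyz = (ryz - rxy * rxz) / dyz if dyz > 0 else 0.0
    total, count = 0.0, 0
    for partial, direct in ((pxy, rxy), (pxz, rxz), (pyz, ryz)):
        if abs(direct) >= delta:
            total += partial / direct
            count += 1
    return total / count if count else 1.0


def _pcit_keep_naive(R: np.ndarray, delta: float = 1e-8) -> np.ndarray:
    """Reference O(n^3) trio loop; returns the boolean keep matrix."""
    m = R.shape[0]
    keep = np.ones((m, m), dtype=bool)
    np.fill_diagonal(keep, False)
    Rl = R.tolist()
    for x, y, z in itertools.combinations(range(m), 3):
        rxy, rxz, ryz = Rl[x][y], Rl[x][z], Rl[y][z]
        eps = trio_tolerance(rxy, rxz, ryz, delta)
        if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
            keep[x][y] = keep[y][x] = False
        if abs(rxz) <= abs(eps * rxy) and abs(rxz) <= abs(eps * ryz):
            keep[x][z] = keep[z][x] = False
        if abs(ryz) <= abs(eps * rxy) and abs(ryz) <= abs(eps * rxz):
            keep[y][z] = keep[z][y] = False
    return keep


def _pcit_keep_fast(R: np.ndarray, delta: float = 1e-8) -> np.ndarray:
    """Vectorised PCIT: for each conditioning node z, test all pairs at once."""
    m = R.shape[0]
    keep = np.ones((m, m), dtype=bool)
    np.fill_diagonal(keep, False)
    one = 1.0 - R * R  # 1 - r^2, elementwise
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(m):
            a = R[:, z]  # r_xz over x
            oz = one[:, z]  # 1 - r_xz^2
            M = R  # r_xy
            den1 = np.sqrt(np.outer(oz, oz))
            p1 = np.where(den1 > 0, (M - np.outer(a, a)) / den1, 0.0)  # r_xy.z
            den2 = np.sqrt(one * oz[None, :])
            p2 = np.where(den2 > 0, (a[:, None] - M * a[None, :]) / den2, 0.0)  # r_xz.y
            den3 = np.sqrt(one * oz[:, None])
            p3 = np.where(den3 > 0, (a[None, :] - M * a[:, None]) / den3, 0.0)  # r_yz.x
            m1 = np.abs(M) >= delta
            m2 = np.abs(a[:, None]) >= delta
            m3 = np.abs(a[None, :]) >= delta
            total = np.where(m1, np.divide(p1, M, where=m1, out=np.zeros_like(p1)), 0.0)
            total = total + np.where(m2, p2 / a[:, None], 0.0)
            total = total + np.where(m3, p3 / a[None, :], 0.0)
            count = m1.astype(np.int64) + m2 + m3
            eps = np.where(count > 0, total / np.maximum(count, 1), 1.0)
            dominated = (np.abs(M) <= np.abs(eps * a[:, None])) & (np.abs(M) <= np.abs(eps * a[None, :]))
            dominated[z, :] = False
            dominated[:, z] = False
            np.fill_diagonal(dominated, False)
            keep &= ~dominated
    return keep


def pcit_filter(corr: CorrelationMatrix, method: str = "fast", delta: float = 1e-8) -> EdgeSet:
    """Apply the PCIT trio-elimination rule; returns the surviving edges.

    The returned edges have not yet been through the significance threshold;
    chain with `significance_filter` for the final network.
    """
    if method not in ("fast", "naive"):
        raise ValueError("method must be 'fast' or 'naive'")
    R = corr.values.to_numpy(dtype=float)
    if R.shape[0] < 3:
        raise ValueError("PCIT needs at least 3 nodes")
    if np.isnan(R).any():
        rows = corr.values.index[np.isnan(R).any(axis=1)].tolist()
        raise ValueError(f"correlation matrix contains NaN for node(s): {rows}")
    keep = _pcit_keep_fast(R, delta) if method == "fast" else _pcit_keep_naive(R, delta)
    return _edges_from_keep(R, list(corr.values.index), keep)


def significance_filter(edges: EdgeSet, n: int, alpha: float = 0.05) -> EdgeSet:
    """Keep edges whose correlation t-test (n-2 df, two-sided) has p < alpha.

    |r| = 1 gives p = 0 (kept, flagged in the 'saturated' column); alpha = 1
    retains every PCIT survivor (identity).
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = edges.df.copy()
    r = df["r"].to_numpy(dtype=float)
    saturated = np.abs(r) >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = np.where(saturated, 0.0, 2.0 * sps.t.sf(np.abs(t), n - 2))
    df["p"] = p
    df["saturated"] = saturated
    keep = np.ones(len(df), dtype=bool) if alpha >= 1 else (p < alpha)
    return EdgeSet(df[keep].reset_index(drop=True))
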