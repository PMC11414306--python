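"""Phenotype-centred neighbourhood analyses and network export.

A phenotype's first neighbours are the nodes sharing a surviving significant
edge with it. Summaries report per-node-type counts and percentages, the
three-way overlap of the DMI/RFI/ADG neighbourhoods (the seven disjoint Venn
regions), and the signed microbe-phenotype edge lists. Networks export as
Cytoscape-ready SIF, GraphML (via networkx) or a plain edge TSV that round
trips losslessly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from ._utils import percentage
from .network import NODE_TYPES, EdgeSet


@dataclass
class NeighbourhoodSummary:
    phenotype: str
    neighbours: list[str]
    n_direct_connections: int  # incident surviving edges of the phenotype node
    type_counts: dict[str, int]
    type_percentages: dict[str, float]
    pct_of_network_nodes: float  # neighbours / nodes with >= 1 edge * 100
    pct_of_network_edges: float  # incident edges / total surviving edges * 100

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "neighbours": self.neighbours,
            "n_first_neighbours": len(self.neighbours),
            "n_direct_connections": self.n_direct_connections,
            "type_counts": self.type_counts,
            "type_percentages": self.type_percentages,
            "pct_of_network_nodes": self.pct_of_network_nodes,
            "pct_of_network_edges": self.pct_of_network_edges,
        }


def first_neighbours(
    edges: EdgeSet, node: str, node_table: pd.DataFrame, decimals: int = 1
) -> NeighbourhoodSummary:
    """Summarise the first-neighbour set of one node.

    Percentages are half-up rounded to `decimals` places; the network-node
    denominator is the count of nodes carrying at least one surviving edge.
    An isolated node yields an empty (zero) summary.
    """
    if node not in node_table.index:
        raise KeyError(f"unknown node {node!r}")
    neigh = edges.neighbours(node)
    connected = set(edges.df["node_a"]) | set(edges.df["node_b"])
    counts = {t: 0 for t in NODE_TYPES}
    for nb in neigh:
        counts[str(node_table.loc[nb, "node_type"])] += 1
    pcts = {t: percentage(c, len(neigh), decimals) for t, c in counts.items()}
    return NeighbourhoodSummary(
        phenotype=node,
        neighbours=neigh,
        n_direct_connections=len(neigh),
        type_counts=counts,
        type_percentages=pcts,
        pct_of_network_nodes=percentage(len(neigh), len(connected), decimals),
        pct_of_network_edges=percentage(len(neigh), len(edges), decimals + 1),
    )


def neighbourhood_overlap(summaries: dict[str, NeighbourhoodSummary]) -> dict[tuple[str, ...], int]:
    """The disjoint region counts of the neighbour sets (all 2^k - 1 regions)."""
    names = sorted(summaries)
    sets = {p: set(summaries[p].neighbours) for p in names}
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(sets[p] for p in combo)) if combo else set()
            outside = set.union(set(), *(sets[p] for p in names if p not in combo))
            regions[combo] = len(inside - outside)
    return regions


def microbe_phenotype_report(
    edges: EdgeSet, node_table: pd.DataFrame, phenotypes: tuple[str, ...] = ("DMI", "RFI", "ADG")
) -> dict:
    """Signed microbial first neighbours per phenotype, plus the shared set."""
    microbe_ids = set(node_table.index[node_table["node_type"] == "microbe"])
    per_phen: dict[str, pd.DataFrame] = {}
    membership: dict[str, dict[str, str]] = {}
    for phen in phenotypes:
        df = edges.df
        hit = df[((df["node_a"] == phen) & df["node_b"].isin(microbe_ids)) | ((df["node_b"] == phen) & df["node_a"].isin(microbe_ids))]
        taxa = [b if a == phen else a for a, b in zip(hit["node_a"], hit["node_b"])]
        rep = pd.DataFrame({"taxon": taxa, "r": hit["r"].to_numpy(), "sign": hit["sign"].to_numpy()})
        rep = rep.sort_values("taxon", kind="mergesort").reset_index(drop=True)
        per_phen[phen] = rep
        for t, s in zip(rep["taxon"], rep["sign"]):
            membership.setdefault(t, {})[phen] = s
    shared = {t: signs for t, signs in sorted(membership.items()) if len(signs) > 1}
    return {"per_phenotype": per_phen, "shared_microbes": shared}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


def export_network(
    edges: EdgeSet, node_table: pd.DataFrame, path: str | Path, format: str = "edge-tsv"
) -> Path:
    """Write the network for downstream tools (e.g. Cytoscape import)."""
    path = Path(path)
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; options: {EXPORT_FORMATS}")
    if format == "sif":
        lines = [f"{a} {s} {b}" for a, s, b in zip(edges.df["node_a"], edges.df["sign"], edges.df["node_b"])]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge-tsv":
        df = edges.df.copy()
        if "p" not in df:
            df["p"] = float("nan")
        df[["node_a", "node_b", "r", "sign", "p"]].to_csv(path, sep="\t", index=False)
    else:
        g = nx.Graph()
        used = set(edges.df["node_a"]) | set(edges.df["node_b"])
        for node in node_table.index:
            if node in used:
                g.add_node(
                    node,
                    node_type=str(node_table.loc[node, "node_type"]),
                    contrasts=str(node_table.loc[node, "contrasts"]),
                    rank=str(node_table.loc[node, "rank"]),
                    lineage=str(node_table.loc[node, "lineage"]),
                )
        for row in edges.df.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, weight=float(row.r), sign=row.sign)
        nx.write_graphml(g, path)
    return path


def read_edge_tsv(path: str | Path) -> EdgeSet:
    """Inverse of the edge-tsv export; reconstructs the EdgeSet."""
    df = pd.read_csv(path, sep="\t")
    required = ["node_a", "node_b", "r", "sign", "p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"edge table missing column(s): {missing}")
    return EdgeSet(df[required])


def write_neighbourhood_report(
    summaries: dict[str, NeighbourhoodSummary],
    overlap: dict[tuple[str, ...], int],
    path: str | Path,
) -> Path:
    path = Path(path)
    payload = {
        "neighbourhoods": {p: s.to_dict() for p, s in sorted(summaries.items())},
        "overlap_regions": {"&".join(k): v for k, v in sorted(overlap.items())},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
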