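"""End-to-end pipeline: simulate or load the cohort, prepare expression and
microbiome profiles, build the PCIT network, and run the downstream analyses.

The JSON run report carries the stage counts (expressed genes, selected genes
per contrast, nodes, surviving edges, neighbourhood sizes, regression paths,
cluster ordering) and is byte-identical across runs with the same config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, expression, microbiome, network, stats
from .config import PipelineConfig
from .simulate import (
    VFA_NAMES,
    CohortDesign,
    SyntheticCohort,
    simulate_cohort,
    write_cohort,
)
from . import io as rio

log = logging.getLogger("rumennet")


@dataclass
class RunResult:
    config: PipelineConfig
    node_table: pd.DataFrame
    edges: network.EdgeSet
    summaries: dict[str, analysis.NeighbourhoodSummary]
    overlap: dict[tuple[str, ...], int]
    microbe_report: dict
    regression_paths: dict[str, stats.RegressionPath]
    clustering: stats.ClusterOrdering | None
    report: dict = field(default_factory=dict)


def load_cohort(input_dir: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by `write_cohort`."""
    d = Path(input_dir)
    phen = rio.read_phenotypes(d / "phenotypes.csv")
    counts = rio.read_counts(d / "gene_counts.tsv")
    abundance, taxonomy = rio.read_taxa(d / "taxa_abundance.tsv")
    vfa = rio.read_vfa(d / "vfa.tsv")
    planted = rio.read_planted(d / "planted_truth.json")
    design = CohortDesign(seed=0)  # layout metadata is not needed downstream
    return SyntheticCohort(design, planted, phen, counts, abundance, taxonomy, vfa)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    cohort: SyntheticCohort | None = None,
    input_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the full analysis chain and (optionally) write all outputs."""
    if cohort is None:
        if input_dir is not None:
            cohort = load_cohort(input_dir)
        else:
            design = CohortDesign(n_per_group=config.n_per_group, seed=config.seed)
            cohort = simulate_cohort(design, n_genes=config.n_genes, n_leaf_taxa=config.n_leaf_taxa)

    # --- expression prep --------------------------------------------------
    cpm = _stage("compute_cpm")(expression.compute_cpm)(cohort.gene_counts)
    kept = expression.filter_expressed(cpm, config.min_cpm, config.min_fraction)
    contrasts = _stage("fit_contrasts")(expression.fit_contrasts)(
        cpm.values.loc[kept], cohort.phenotypes
    )
    deg_lists = {
        c: expression.select_top_fraction(res, config.de_fraction) for c, res in contrasts.items()
    }

    # --- microbiome / VFA prep -------------------------------------------
    rel = microbiome.relative_abundance(cohort.taxa_abundance)
    if config.min_prevalence > 0:
        present = (rel > 0).mean(axis=1) >= config.min_prevalence
        rel = rel.loc[present]
    taxa_profiles = microbiome.transform_abundance(
        rel, method=config.taxa_transform, pseudocount=config.taxa_pseudocount
    )
    gene_profiles = np.log2(cpm.values.loc[sorted(set().union(*deg_lists.values()))] + 0.5)
    stack = _stage("align_samples")(microbiome.align_samples)(
        gene_profiles, taxa_profiles, cohort.vfa, cohort.phenotypes
    )

    # --- network ----------------------------------------------------------
    taxonomy = cohort.taxonomy.loc[stack.taxa.index]
    node_table = network.assemble_nodes(
        deg_lists, taxonomy, vfa_names=list(stack.vfa.index), phenotype_names=("DMI", "RFI", "ADG")
    )
    profiles = pd.concat([stack.genes, stack.taxa, stack.vfa, stack.phenotype_profiles()])
    profiles = profiles.loc[node_table.index]
    corr = _stage("compute_correlations")(network.compute_correlations)(profiles)
    corr = network.drop_constant_nodes(corr)
    node_table = node_table.loc[corr.values.index]
    pcit_edges = _stage("pcit_filter")(network.pcit_filter)(corr, delta=config.pcit_delta)
    edges = network.significance_filter(pcit_edges, n=corr.n_samples, alpha=config.alpha)

    # --- neighbourhood analyses -------------------------------------------
    summaries = {
        p: analysis.first_neighbours(edges, p, node_table) for p in ("DMI", "RFI", "ADG")
    }
    overlap = analysis.neighbourhood_overlap(summaries)
    microbe_report = analysis.microbe_phenotype_report(edges, node_table)

    # --- stepwise regression / clustering ---------------------------------
    phen_cols = {"DMI": "dmi", "RFI": "rfi", "ADG": "adg"}
    connected_taxa = sorted(
        set().union(*(set(rep["taxon"]) for rep in microbe_report["per_phenotype"].values()))
    )
    regression_paths: dict[str, stats.RegressionPath] = {}
    clustering = None
    if connected_taxa:
        cand = stack.taxa.loc[connected_taxa]
        for phen, col in phen_cols.items():
            y = stack.phenotypes[col].rename(phen)
            regression_paths[phen] = stats.stepwise_r2(
                y, cand, target_r2=config.stepwise_target_r2, tol=config.stepwise_tol
            )
        cluster_profiles = pd.concat([stack.phenotype_profiles(), cand])
        if len(cluster_profiles) >= 2:
            clustering = stats.hierarchical_cluster(cluster_profiles, linkage=config.cluster_linkage)

    # --- report -----------------------------------------------------------
    report = {
        "config": config.to_dict(),
        "n_samples": int(len(stack.sample_ids)),
        "expressed_genes": {c: int(res.expressed_gene_count) for c, res in contrasts.items()},
        "selected_genes": {c: len(g) for c, g in deg_lists.items()},
        "n_nodes": int(len(node_table)),
        "n_nodes_by_type": {
            t: int((node_table["node_type"] == t).sum()) for t in network.NODE_TYPES
        },
        "n_edges_pcit": int(len(pcit_edges)),
        "n_edges_significant": int(len(edges)),
        "n_connected_nodes": int(len(set(edges.df["node_a"]) | set(edges.df["node_b"]))),
        "neighbourhoods": {p: s.to_dict() for p, s in summaries.items()},
        "overlap_regions": {"&".join(k): v for k, v in sorted(overlap.items())},
        "stepwise": {
            p: {
                "selected": rp.selected,
                "cumulative_r2": round(rp.cumulative_r2, 6),
                "stopping_reason": rp.stopping_reason,
            }
            for p, rp in regression_paths.items()
        },
        "cluster_leaf_order": clustering.leaf_order if clustering else [],
    }

    # --- outputs ----------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        node_table.to_csv(out / "nodes.tsv", sep="\t")
        suffix = {"edge-tsv": "edges.tsv", "sif": "network.sif", "graphml": "network.graphml"}
        for fmt in config.export_formats:
            analysis.export_network(edges, node_table, out / suffix[fmt], format=fmt)
        analysis.write_neighbourhood_report(summaries, overlap, out / "neighbourhoods.json")
        (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return RunResult(
        config=config,
        node_table=node_table,
        edges=edges,
        summaries=summaries,
        overlap=overlap,
        microbe_report=microbe_report,
        regression_paths=regression_paths,
        clustering=clustering,
        report=report,
    )


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> SyntheticCohort:
    """Simulate a cohort under the config and write its tables."""
    design = CohortDesign(n_per_group=config.n_per_group, seed=config.seed)
    cohort = simulate_cohort(design, n_genes=config.n_genes, n_leaf_taxa=config.n_leaf_taxa)
    write_cohort(cohort, out_dir)
    return cohort
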