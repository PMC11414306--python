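"""Synthetic multi-omic cohort generator with known planted structure.

Emulates the desk-scale shape of a feed-efficiency cattle study: two breeds,
contrasting diet phases and High/Low residual-feed-intake (RFI) groups; liver
gene counts with negative-binomial noise and planted fold changes; compositional
rumen taxa abundances organised in clades (internal taxonomy rows are sums of
their leaves); and 13 rumen volatile-fatty-acid (VFA) variables arithmetically
tied to their component acids. Every generator is deterministic under a fixed
seed, and the planted structure is returned so downstream recovery can be
scored against ground truth.

The observation unit is animal x diet phase: each animal contributes one
observation per diet, and repeated measures are treated as independent
observations, mirroring how the downstream network pools phases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import child_rng

RANKS = ("phylum", "class", "order", "family", "genus", "species")
PHENOTYPES = ("DMI", "RFI", "ADG")

#: The 13 rumen fermentation variables, in their canonical order. The last
#: three of the measured set (total SCFA, the acetic:propionic ratio and
#: DL-lactic acid) are derived from the others.
VFA_NAMES = (
    "acetic",
    "propionic",
    "isobutyric",
    "butyric",
    "isovaleric",
    "valeric",
    "total_scfa",
    "acetic_propionic_ratio",
    "d_lactic",
    "l_lactic",
    "dl_lactic",
    "g_lactic",
    "ammonia",
)

#: Acids measured directly (linear functions of producer taxa + noise).
COMPONENT_ACIDS = ("acetic", "propionic", "isobutyric", "butyric", "isovaleric", "valeric")
MEASURED_VFA = COMPONENT_ACIDS + ("d_lactic", "l_lactic", "g_lactic", "ammonia")

# Baseline concentrations, roughly mmol/L for the acids and NH3; lactic acids
# are minor fermentation products in a healthy rumen.
_VFA_BASELINE = {
    "acetic": 60.0,
    "propionic": 22.0,
    "isobutyric": 1.2,
    "butyric": 12.0,
    "isovaleric": 1.8,
    "valeric": 1.5,
    "d_lactic": 0.6,
    "l_lactic": 0.7,
    "g_lactic": 0.3,
    "ammonia": 8.0,
}


@dataclass(frozen=True)
class CohortDesign:
    """Factorial cohort layout: breeds x diets x RFI groups x replicates."""

    n_per_group: int = 10
    breeds: tuple[str, ...] = ("CH", "HF")
    diets: tuple[str, ...] = ("high_concentrate", "zero_grazed_grass")
    rfi_groups: tuple[str, ...] = ("High", "Low")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("breeds", "diets", "rfi_groups"):
            labels = getattr(self, name)
            if len(labels) < 1 or len(set(labels)) != len(labels):
                raise ValueError(f"{name} must be non-empty unique labels")

    @property
    def n_observations(self) -> int:
        return self.n_per_group * len(self.breeds) * len(self.diets) * len(self.rfi_groups)


def observation_grid(design: CohortDesign) -> pd.DataFrame:
    """The deterministic sample layout shared by all generators.

    One row per observation (animal x diet). Sample ids are stable strings so
    matrices produced by the separate generators align by construction.
    """
    rows = []
    for breed in design.breeds:
        for group in design.rfi_groups:
            for k in range(design.n_per_group):
                animal = f"{breed}_{group}_{k:02d}"
                for diet in design.diets:
                    rows.append(
                        {
                            "sample_id": f"{animal}_{diet}",
                            "animal": animal,
                            "breed": breed,
                            "diet": diet,
                            "rfi_group": group,
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Planted structure
# ---------------------------------------------------------------------------


@dataclass
class PlantedStructure:
    """Ground truth wired into a simulated cohort.

    de_genes        contrast -> {gene index: log2 fold change}
    phenotype_taxa  phenotype -> {leaf taxon id: signed effect size on the
                    log-abundance scale, in SD units of the phenotype}
    vfa_producers   measured VFA variable -> producer leaf taxon ids
    taxonomy        one row per taxon (leaves and internal clade rows) with
                    rank, parent and lineage columns
    """

    de_genes: dict[str, dict[int, float]]
    phenotype_taxa: dict[str, dict[str, float]]
    vfa_producers: dict[str, tuple[str, ...]]
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        for contrast, genes in self.de_genes.items():
            for idx, lfc in genes.items():
                if not math.isfinite(lfc):
                    raise ValueError(f"non-finite log2FC for gene {idx} ({contrast})")
        for phen, taxa in self.phenotype_taxa.items():
            for taxon, eff in taxa.items():
                if not math.isfinite(eff) or eff == 0:
                    raise ValueError(f"effect for {taxon} ({phen}) must be finite and non-zero")
        self._check_tree()

    @property
    def clade_tree(self) -> dict[str, str]:
        """child taxon id -> parent taxon id (roots absent)."""
        tax = self.taxonomy
        return {t: p for t, p in zip(tax.index, tax["parent"]) if isinstance(p, str) and p}

    def leaves(self) -> list[str]:
        parents = set(self.clade_tree.values())
        return [t for t in self.taxonomy.index if t not in parents]

    def _check_tree(self) -> None:
        tree = self.clade_tree
        known = set(self.taxonomy.index)
        for child, parent in tree.items():
            if parent not in known:
                raise ValueError(f"parent {parent!r} of {child!r} is not a taxonomy row")
        for start in tree:
            seen = {start}
            node = start
            while node in tree:
                node = tree[node]
                if node in seen:
                    raise ValueError(f"cycle in clade tree involving {node!r}")
                seen.add(node)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "de_genes": {c: {str(i): v for i, v in g.items()} for c, g in self.de_genes.items()},
            "phenotype_taxa": self.phenotype_taxa,
            "vfa_producers": {k: list(v) for k, v in self.vfa_producers.items()},
            "taxonomy": self.taxonomy.reset_index().to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlantedStructure":
        tax = pd.DataFrame(d["taxonomy"]).set_index("taxon_id")
        return cls(
            de_genes={c: {int(i): float(v) for i, v in g.items()} for c, g in d["de_genes"].items()},
            phenotype_taxa={p: dict(t) for p, t in d["phenotype_taxa"].items()},
            vfa_producers={k: tuple(v) for k, v in d["vfa_producers"].items()},
            taxonomy=tax,
        )


def default_taxonomy(n_leaf_taxa: int) -> pd.DataFrame:
    """A balanced clade tree: species leaves grouped pairwise up five ranks.

    Returns a frame indexed by taxon_id with rank, parent and lineage columns;
    internal rows (genus..phylum) will later hold sums of their leaf rows.
    """
    if n_leaf_taxa < 4:
        raise ValueError("n_leaf_taxa must be >= 4")
    prefixes = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g", "species": "sp"}
    # number of nodes per rank, halving upward
    counts = {"species": n_leaf_taxa}
    prev = n_leaf_taxa
    for rank in ("genus", "family", "order", "class", "phylum"):
        prev = max(1, math.ceil(prev / 2))
        counts[rank] = prev

    def node_id(rank: str, i: int) -> str:
        return f"{prefixes[rank]}{i:03d}"

    rows = []
    order = ("species", "genus", "family", "order", "class", "phylum")
    for ri, rank in enumerate(order):
        parent_rank = order[ri + 1] if ri + 1 < len(order) else None
        for i in range(counts[rank]):
            if parent_rank is None:
                parent = ""
            else:
                parent = node_id(parent_rank, min(i // 2, counts[parent_rank] - 1))
            rows.append({"taxon_id": node_id(rank, i), "rank": rank, "parent": parent})
    tax = pd.DataFrame(rows).set_index("taxon_id")
    # lineage: root-to-node path
    lineages = {}
    parent_of = dict(zip(tax.index, tax["parent"]))
    for t in tax.index:
        path = [t]
        node = t
        while parent_of.get(node):
            node = parent_of[node]
            path.append(node)
        lineages[t] = ";".join(reversed(path))
    tax["lineage"] = pd.Series(lineages)
    return tax


def default_planted_structure(
    n_genes: int = 2000,
    n_leaf_taxa: int = 30,
    n_de_per_contrast: int = 30,
    log2fc: float = 2.0,
    taxa_effect: float = 0.8,
) -> PlantedStructure:
    """Deterministic default ground truth.

    DE genes occupy disjoint leading index blocks per contrast with alternating
    fold-change sign; phenotype-linked taxa are disjoint leaf sets (DMI
    positive, RFI negative, ADG negative — the signs the downstream recovery
    tests assert); every measured VFA gets a distinct pair of producer leaves,
    cycling when leaves run short.
    """
    if 3 * n_de_per_contrast > n_genes:
        raise ValueError("too many planted DE genes for n_genes")
    de = {}
    for ci, contrast in enumerate(("rfi", "breed", "diet")):
        start = ci * n_de_per_contrast
        de[contrast] = {
            g: (log2fc if (g - start) % 2 == 0 else -log2fc)
            for g in range(start, start + n_de_per_contrast)
        }
    tax = default_taxonomy(n_leaf_taxa)
    parents = set(p for p in tax["parent"] if p)
    leaves = [t for t in tax.index if t not in parents]
    picks = {"DMI": (leaves[0:3], +1.0), "RFI": (leaves[3:6], -1.0), "ADG": (leaves[6:8], -1.0)}
    phenotype_taxa = {
        phen: {t: sign * taxa_effect for t in chosen} for phen, (chosen, sign) in picks.items()
    }
    producers = {}
    pool = leaves[8:] or leaves
    for i, vfa in enumerate(MEASURED_VFA):
        producers[vfa] = (pool[(2 * i) % len(pool)], pool[(2 * i + 1) % len(pool)])
    return PlantedStructure(
        de_genes=de, phenotype_taxa=phenotype_taxa, vfa_producers=producers, taxonomy=tax
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeParams:
    """Generating model for intake: DMI = b0 + b1*ADG + b2*MW + group shift + noise.

    group_shift is applied divergently: +shift for High-RFI, -shift for
    Low-RFI animals, so the expected High-Low DMI separation is 2*shift (kg
    DM/day). MW is mid-test metabolic weight, live weight^0.75 (kg^0.75).
    """

    intercept: float = 0.5
    b_adg: float = 1.2  # kg DM per kg daily gain
    b_mw: float = 0.08  # kg DM per kg^0.75
    group_shift: float = 0.8  # kg DM/day, divergent
    noise_sd: float = 0.5  # kg DM/day
    adg_mean: float = 1.4  # kg/day
    adg_sd: float = 0.2
    live_weight_means: tuple[float, ...] = (485.0, 401.0)  # per breed, kg
    live_weight_sd: float = 35.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_phenotypes(design: CohortDesign, params: PhenotypeParams = PhenotypeParams()) -> pd.DataFrame:
    """Simulate the phenotype/design table and derive RFI as a residual.

    RFI is the within-breed least-squares residual of DMI on ADG and metabolic
    weight, so by construction it sums to zero and is orthogonal to both
    regressors inside each breed. High-RFI animals eat more than their model
    prediction; Low-RFI animals eat less.
    """
    rng = child_rng(design.seed, 0)
    grid = observation_grid(design)
    n = len(grid)
    lw_mean = {b: params.live_weight_means[i % len(params.live_weight_means)] for i, b in enumerate(design.breeds)}
    lw = np.array([lw_mean[b] for b in grid["breed"]]) + rng.normal(0, params.live_weight_sd, n)
    lw = np.clip(lw, 150.0, None)
    adg = params.adg_mean + rng.normal(0, params.adg_sd, n)
    mw = lw**0.75
    shift = np.where(np.asarray(grid["rfi_group"]) == design.rfi_groups[0], params.group_shift, -params.group_shift)
    dmi = (
        params.intercept
        + params.b_adg * adg
        + params.b_mw * mw
        + shift
        + (rng.normal(0, params.noise_sd, n) if params.noise_sd > 0 else 0.0)
    )
    table = grid.copy()
    table["dmi"] = dmi
    table["adg"] = adg
    table["metabolic_weight"] = mw
    table["rfi"] = np.nan
    for breed in design.breeds:
        mask = table["breed"] == breed
        nb = int(mask.sum())
        if nb < 4:
            raise ValueError(
                f"breed {breed!r} has {nb} observations; the within-breed RFI fit "
                "needs at least regressors + 1 = 4"
            )
        X = np.column_stack([np.ones(nb), table.loc[mask, "adg"], table.loc[mask, "metabolic_weight"]])
        y = table.loc[mask, "dmi"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        table.loc[mask, "rfi"] = y - X @ beta
    return table


# ---------------------------------------------------------------------------
# Gene counts
# ---------------------------------------------------------------------------


def _contrast_codes(grid: pd.DataFrame, design: CohortDesign) -> dict[str, np.ndarray]:
    """+1/-1 coding of the three two-level contrasts, first design level = +1."""
    return {
        "rfi": np.where(grid["rfi_group"] == design.rfi_groups[0], 1.0, -1.0),
        "breed": np.where(grid["breed"] == design.breeds[0], 1.0, -1.0),
        "diet": np.where(grid["diet"] == design.diets[0], 1.0, -1.0),
    }


def simulate_gene_counts(
    design: CohortDesign,
    planted: PlantedStructure,
    n_genes: int = 2000,
    nb_dispersion: float = 0.1,
    libsize_range: tuple[float, float] = (1e6, 3e6),
) -> pd.DataFrame:
    """Negative-binomial gene counts (genes x observations) with planted DE.

    Gene-wise baseline proportions are log-normal; a planted gene's mean is
    multiplied by 2^(lfc/2 * code) so the between-group fold change equals
    2^lfc; per-sample means are rescaled so every library hits its drawn size.
    Counts are gamma-Poisson draws with shared dispersion (variance
    mu + dispersion*mu^2); dispersion below 1e-12 degenerates to Poisson.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    for contrast, genes in planted.de_genes.items():
        bad = [g for g in genes if g >= n_genes or g < 0]
        if bad:
            raise ValueError(f"planted gene indices out of range for contrast {contrast!r}: {bad}")
    rng = child_rng(design.seed, 1)
    grid = observation_grid(design)
    codes = _contrast_codes(grid, design)
    n_obs = len(grid)
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    log2mult = np.zeros((n_genes, n_obs))
    for contrast, genes in planted.de_genes.items():
        code = codes[contrast]
        for g, lfc in genes.items():
            log2mult[g] += 0.5 * lfc * code
    libsizes = rng.uniform(libsize_range[0], libsize_range[1], n_obs)
    mu = base[:, None] * np.exp2(log2mult)
    mu = mu / mu.sum(axis=0, keepdims=True) * libsizes[None, :]
    if nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mu * nb_dispersion))
    return pd.DataFrame(
        counts.astype(np.int64),
        index=[f"gene{i:05d}" for i in range(n_genes)],
        columns=list(grid.index),
    )


# ---------------------------------------------------------------------------
# Microbiome
# ---------------------------------------------------------------------------


def simulate_microbiome(
    design: CohortDesign,
    planted: PlantedStructure,
    phenotypes: pd.DataFrame | None = None,
    log_noise_sd: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compositional taxa abundances (taxa rows x samples) plus the taxonomy.

    Leaf log-abundances get a planted contribution effect * z(phenotype) per
    linked phenotype, then log-normal noise, and are closed to the simplex per
    sample. Internal clade rows are exact sums of their leaf descendants, so
    members of one clade co-vary by construction.
    """
    leaves = planted.leaves()
    if len(leaves) < 4:
        raise ValueError("need at least 4 leaf taxa")
    if phenotypes is None:
        phenotypes = simulate_phenotypes(design)
    rng = child_rng(design.seed, 2)
    samples = phenotypes.index
    n = len(samples)
    base = rng.normal(0.0, 1.0, len(leaves))
    logA = base[:, None] + rng.normal(0.0, log_noise_sd, (len(leaves), n))
    phen_cols = {"DMI": "dmi", "RFI": "rfi", "ADG": "adg"}
    for phen, taxa in planted.phenotype_taxa.items():
        v = phenotypes[phen_cols[phen]].to_numpy(dtype=float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros(n)
        for taxon, eff in taxa.items():
            if taxon not in leaves:
                raise ValueError(f"planted taxon {taxon!r} is not a leaf")
            logA[leaves.index(taxon)] += eff * z
    A = np.exp(logA)
    A /= A.sum(axis=0, keepdims=True)
    leaf_df = pd.DataFrame(A, index=leaves, columns=list(samples))
    # aggregate leaves bottom-up so parents are exact sums of children
    tax = planted.taxonomy
    tree = planted.clade_tree
    rows: dict[str, np.ndarray] = {t: leaf_df.loc[t].to_numpy() for t in leaves}
    pending = [t for t in tax.index if t not in rows]
    children: dict[str, list[str]] = {}
    for child, parent in tree.items():
        children.setdefault(parent, []).append(child)
    while pending:
        progressed = False
        for t in list(pending):
            kids = children.get(t, [])
            if all(k in rows for k in kids):
                rows[t] = np.sum([rows[k] for k in kids], axis=0) if kids else np.zeros(n)
                pending.remove(t)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by PlantedStructure
            raise ValueError("clade tree could not be aggregated (cycle?)")
    abund = pd.DataFrame({t: rows[t] for t in tax.index}, index=list(samples)).T
    abund.index.name = "taxon_id"
    return abund, tax.copy()


# ---------------------------------------------------------------------------
# VFAs
# ---------------------------------------------------------------------------


def simulate_vfa(
    abundance: pd.DataFrame,
    planted: PlantedStructure,
    noise_scale: float = 0.05,
    seed: int = 0,
    on_zero_propionic: str = "regenerate",
) -> pd.DataFrame:
    """The 13 VFA variables (rows) per sample, derived quantities computed last.

    Each measured acid is baseline * (0.5 + 5 * sum of producer abundances)
    plus Gaussian noise proportional to its baseline, truncated at zero. Then,
    exactly: total_scfa = sum of the six component acids, the acetic:propionic
    ratio, and dl_lactic = d_lactic + l_lactic, so the arithmetic identities
    hold whatever the noise did.
    """
    if on_zero_propionic not in ("regenerate", "error"):
        raise ValueError("on_zero_propionic must be 'regenerate' or 'error'")
    missing = [t for acids in planted.vfa_producers.values() for t in acids if t not in abundance.index]
    if missing:
        raise ValueError(f"producer taxa absent from abundance matrix: {sorted(set(missing))}")
    rng = np.random.default_rng(seed)
    samples = abundance.columns
    vals: dict[str, np.ndarray] = {}
    for acid in MEASURED_VFA:
        producers = list(planted.vfa_producers.get(acid, ()))
        signal = abundance.loc[producers].sum(axis=0).to_numpy() if producers else np.zeros(len(samples))
        conc = _VFA_BASELINE[acid] * (0.5 + 5.0 * signal)
        if noise_scale > 0:
            conc = conc + rng.normal(0.0, noise_scale * _VFA_BASELINE[acid], len(samples))
        conc = np.clip(conc, 0.0, None)
        if acid == "propionic":
            tries = 0
            while np.any(conc == 0.0):
                if on_zero_propionic == "error" or tries >= 100:
                    raise ValueError("propionic acid hit zero; acetic:propionic ratio undefined")
                zero = conc == 0.0
                conc[zero] = np.clip(
                    _VFA_BASELINE[acid] * (0.5 + 5.0 * signal[zero])
                    + rng.normal(0.0, noise_scale * _VFA_BASELINE[acid], int(zero.sum())),
                    0.0,
                    None,
                )
                tries += 1
        vals[acid] = conc
    vals["total_scfa"] = np.sum([vals[a] for a in COMPONENT_ACIDS], axis=0)
    vals["acetic_propionic_ratio"] = vals["acetic"] / vals["propionic"]
    vals["dl_lactic"] = vals["d_lactic"] + vals["l_lactic"]
    return pd.DataFrame({name: vals[name] for name in VFA_NAMES}, index=list(samples)).T


# ---------------------------------------------------------------------------
# Orchestration + disk round trip
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    design: CohortDesign
    planted: PlantedStructure
    phenotypes: pd.DataFrame
    gene_counts: pd.DataFrame
    taxa_abundance: pd.DataFrame
    taxonomy: pd.DataFrame
    vfa: pd.DataFrame


def simulate_cohort(
    design: CohortDesign,
    planted: PlantedStructure | None = None,
    n_genes: int = 2000,
    n_leaf_taxa: int = 30,
    phenotype_params: PhenotypeParams = PhenotypeParams(),
    nb_dispersion: float = 0.1,
    vfa_noise: float = 0.05,
) -> SyntheticCohort:
    """Generate the four linked tables with one consistent planted structure."""
    if planted is None:
        planted = default_planted_structure(n_genes=n_genes, n_leaf_taxa=n_leaf_taxa)
    phen = simulate_phenotypes(design, phenotype_params)
    genes = simulate_gene_counts(design, planted, n_genes=n_genes, nb_dispersion=nb_dispersion)
    abund, tax = simulate_microbiome(design, planted, phenotypes=phen)
    vfa = simulate_vfa(abund, planted, noise_scale=vfa_noise, seed=design.seed + 3)
    return SyntheticCohort(design, planted, phen, genes, abund, tax, vfa)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text tables with shared sample ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.csv",
        "gene_counts": out / "gene_counts.tsv",
        "taxa_abundance": out / "taxa_abundance.tsv",
        "vfa": out / "vfa.tsv",
        "planted": out / "planted_truth.json",
    }
    cohort.phenotypes.to_csv(paths["phenotypes"])
    cohort.gene_counts.to_csv(paths["gene_counts"], sep="\t")
    taxa = cohort.taxa_abundance.copy()
    taxa.insert(0, "rank", cohort.taxonomy["rank"])
    taxa.insert(1, "lineage", cohort.taxonomy["lineage"])
    taxa.to_csv(paths["taxa_abundance"], sep="\t")
    cohort.vfa.to_csv(paths["vfa"], sep="\t")
    paths["planted"].write_text(json.dumps(cohort.planted.to_dict(), indent=1, sort_keys=True))
    return paths
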