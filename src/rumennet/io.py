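"""Typed table I/O with strict schema checks; all formats are plain text."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import PlantedStructure

PHENOTYPE_COLUMNS = ["animal", "breed", "diet", "rfi_group", "dmi", "adg", "metabolic_weight", "rfi"]
TAXA_META_COLUMNS = ["rank", "lineage"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    _require(df, PHENOTYPE_COLUMNS, "phenotype table")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    _require(table, PHENOTYPE_COLUMNS, "phenotype table")
    table.to_csv(path)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError("gene count table is empty")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_taxa(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxa TSV -> (abundance matrix, taxonomy frame with rank/lineage)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _require(df, TAXA_META_COLUMNS, "taxa table")
    taxonomy = df[TAXA_META_COLUMNS].copy()
    abundance = df.drop(columns=TAXA_META_COLUMNS)
    return abundance, taxonomy


def write_taxa(abundance: pd.DataFrame, taxonomy: pd.DataFrame, path: str | Path) -> None:
    out = abundance.copy()
    out.insert(0, "rank", taxonomy["rank"])
    out.insert(1, "lineage", taxonomy["lineage"])
    out.to_csv(path, sep="\t")


def read_vfa(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_vfa(vfa: pd.DataFrame, path: str | Path) -> None:
    vfa.to_csv(path, sep="\t")


def read_planted(path: str | Path) -> PlantedStructure:
    return PlantedStructure.from_dict(json.loads(Path(path).read_text()))
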