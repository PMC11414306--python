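"""Microbiome and VFA preparation: closure to relative abundance, log/CLR
transforms, and alignment of all omic tables to a shared sample set."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def relative_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Close each sample column to the unit simplex; zeros stay zero."""
    sums = matrix.sum(axis=0)
    bad = sums[sums <= 0]
    if len(bad):
        raise ValueError(f"all-zero sample(s): {list(bad.index)}")
    return matrix / sums


def transform_abundance(
    simplex: pd.DataFrame, method: str = "log10", pseudocount: float = 1e-6
) -> pd.DataFrame:
    """log10(x + pseudocount), or per-sample centred log-ratio (clr).

    The default log10 transform with a 1e-6 pseudocount keeps zeros finite at
    -6; clr additionally removes the compositional constraint by centring the
    log abundances within each sample.
    """
    if method not in ("log10", "clr"):
        raise ValueError("method must be 'log10' or 'clr'")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if method == "log10":
        return np.log10(simplex + pseudocount)
    sums = simplex.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        warnings.warn("clr input is not closed to the simplex; closing first")
        simplex = relative_abundance(simplex)
    logx = np.log(simplex + pseudocount)
    return logx - logx.mean(axis=0)


@dataclass
class OmicsStack:
    """Sample-aligned node profiles: the input to correlation/PCIT.

    All three matrices are features x samples in identical sample order, and
    phenotypes is samples x columns (must include dmi, rfi, adg). Matrices are
    expected to be network-ready (genes on the log2 CPM scale, taxa already
    transformed, VFAs in raw concentration units).
    """

    genes: pd.DataFrame
    taxa: pd.DataFrame
    vfa: pd.DataFrame
    phenotypes: pd.DataFrame
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.genes.columns

    def phenotype_profiles(self) -> pd.DataFrame:
        """DMI/RFI/ADG as profile rows matching the matrix orientation."""
        prof = self.phenotypes[["dmi", "rfi", "adg"]].T
        prof.index = ["DMI", "RFI", "ADG"]
        return prof


def align_samples(
    genes: pd.DataFrame,
    taxa: pd.DataFrame,
    vfa: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> OmicsStack:
    """Restrict all four tables to the shared sample ids, in sorted order.

    The result is invariant to the input column orderings, and the per-table
    drop report records which samples each table lost.
    """
    ids = {
        "genes": set(genes.columns),
        "taxa": set(taxa.columns),
        "vfa": set(vfa.columns),
        "phenotypes": set(phenotypes.index),
    }
    shared = sorted(set.intersection(*ids.values()))
    if not shared:
        detail = {k: sorted(v)[:10] for k, v in ids.items()}
        raise ValueError(f"no shared sample ids across tables; per-table ids (head): {detail}")
    dropped = {name: sorted(v - set(shared)) for name, v in ids.items()}
    return OmicsStack(
        genes=genes[shared],
        taxa=taxa[shared],
        vfa=vfa[shared],
        phenotypes=phenotypes.loc[shared],
        dropped=dropped,
    )
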