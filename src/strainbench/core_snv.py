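"""Core biallelic SNV site selection from a genome panel.

Given a genomes x sites allele matrix (0 = reference, 1 = alternate,
missing allowed), retain the sites that are (a) *core* — callable in at
least ``ceil(core_fraction * n_genomes)`` genomes — and (b) *biallelic
SNVs* — exactly two alleles observed, each in at least
``min_allele_genomes`` genomes. With the defaults (95% core presence,
minor allele in >= 2 genomes) a 137-genome panel yields cutoffs of 131
callable genomes and 2 minor-allele genomes.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "core_presence_cutoff",
    "select_core_biallelic_sites",
    "read_allele_matrix",
    "write_site_list",
]


def core_presence_cutoff(n_genomes: int, core_fraction: float = 0.95) -> int:
    """Minimum number of callable genomes for a site to count as core."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0.0 < core_fraction <= 1.0:
        raise ValueError("core_fraction must lie in (0, 1]")
    return math.ceil(core_fraction * n_genomes)


def select_core_biallelic_sites(
    matrix: pd.DataFrame,
    core_fraction: float = 0.95,
    min_allele_genomes: int = 2,
) -> list[int]:
    """Indices (column positions) of core biallelic SNV sites.

    ``matrix``: genomes x sites with allele codes (typically 0/1) and NaN
    for missing calls. A site is kept when its callable-genome count meets
    the core cutoff and exactly two distinct alleles are observed, both in
    at least ``min_allele_genomes`` genomes; monoallelic and multi-allelic
    sites are dropped.
    """
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("allele matrix must be non-empty")
    if min_allele_genomes < 1:
        raise ValueError("min_allele_genomes must be >= 1")
    cutoff = core_presence_cutoff(matrix.shape[0], core_fraction)
    values = matrix.to_numpy(dtype=float)
    kept: list[int] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        called = col[~np.isnan(col)]
        if called.size < cutoff:
            continue
        alleles, counts = np.unique(called, return_counts=True)
        if alleles.size != 2:
            continue
        if counts.min() >= min_allele_genomes:
            kept.append(j)
    return kept


def read_allele_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV allele matrix (rows = genomes, columns = sites, NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"empty allele matrix in {path}")
    return df


def write_site_list(
    sites: list[int], matrix: pd.DataFrame, path: str | Path
) -> None:
    pd.DataFrame(
        {"site_index": sites, "site_id": [matrix.columns[j] for j in sites]}
    ).to_csv(path, sep="\t", index=False)
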