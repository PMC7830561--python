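"""DEG filtering and the joins between DEG sets and (important) rSNPs.

A gene is up-regulated when log2FC > 2 with adjusted p < 0.05, and
down-regulated when log2FC < -2 with adjusted p < 0.05; both inequalities
are strict and rows with missing adjusted p are never significant.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import pandas as pd

from .errors import ParameterError

__all__ = [
    "filter_degs",
    "degs_with_rsnps",
    "important_rsnps_per_tissue",
    "venn_counts",
]


def filter_degs(
    deg_table: pd.DataFrame, lfc: float = 2.0, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split a DE results table into (up, down) significant gene sets.

    Boundary rows (log2FC exactly +/-lfc, or padj exactly alpha) are
    excluded; NA padj is excluded.
    """
    sig = deg_table["padj"] < alpha  # NaN compares False
    up = set(deg_table.loc[sig & (deg_table["log2FoldChange"] > lfc), "gene"])
    down = set(deg_table.loc[sig & (deg_table["log2FoldChange"] < -lfc), "gene"])
    return up, down


def degs_with_rsnps(
    deg_sets: Mapping[str, set[str]],
    rsnp_gene_map: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per tissue: DEGs with >= 1 promoter rSNP, with per-gene rSNP counts.

    ``rsnp_gene_map`` needs columns ``snp_id`` and ``gene_id`` (one row per
    rSNP x host gene, e.g. from :func:`rsnpscan.rsnp.annotate_rsnp_positions`).
    """
    per_gene = (
        rsnp_gene_map.groupby("gene_id")["snp_id"].nunique().rename("n_rsnps")
    )
    out = {}
    for tissue, genes in deg_sets.items():
        hit = per_gene[per_gene.index.isin(genes)]
        out[tissue] = (
            hit.reset_index()
            .rename(columns={"gene_id": "gene"})
            .sort_values("gene")
            .reset_index(drop=True)
        )
    return out


def important_rsnps_per_tissue(
    important_set: set[str],
    rsnp_gene_map: pd.DataFrame,
    deg_sets: Mapping[str, set[str]],
) -> dict[str, pd.DataFrame]:
    """Restrict important rSNPs to promoters of each tissue's DEGs.

    Output rows are rSNP x gene pairs; both the SNP-level and SNP x gene
    tallies are recoverable from them (``snp_id`` may repeat across genes).
    """
    imp = rsnp_gene_map[rsnp_gene_map["snp_id"].isin(important_set)]
    out = {}
    for tissue, genes in deg_sets.items():
        rows = imp[imp["gene_id"].isin(genes)]
        out[tissue] = (
            rows.loc[:, ["snp_id", "gene_id"]]
            .drop_duplicates()
            .sort_values(["snp_id", "gene_id"])
            .reset_index(drop=True)
        )
    return out


def venn_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every non-empty intersection region of k sets.

    Keys are tuples of set names; the value for key (a, b) is the number of
    elements in exactly a and b (and no other set).  Values sum to the size
    of the union.
    """
    names = list(sets)
    if len(names) < 2:
        raise ParameterError("venn_counts needs >= 2 sets")
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
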