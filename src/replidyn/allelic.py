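"""Haplotype/allele-specific expression and replication-timing analysis.

Covers the informative-gene filter on SNP-containing read totals, the
median-ratio classification into monoallelic / biased / biallelic
categories (4- and 5-class schemes), per-bin two-sided Fisher exact tests
for allelic RT asynchrony, and the linkage of expression categories to the
allelic mid-S RT difference over each gene body.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, StructuralError
from .grid import BinGrid
from .rtcore import MISSING, REPLICATED, UNREPLICATED

__all__ = [
    "informative_genes",
    "allelic_ratios",
    "classify_allelic",
    "allelic_rt_fisher",
    "link_ratio_to_rt",
    "FOUR_CLASS",
    "FIVE_CLASS",
]

FOUR_CLASS = "four_class"
FIVE_CLASS = "five_class"


def informative_genes(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_total: int = 6,
    min_cell_frac: float = 0.5,
) -> pd.Index:
    """Genes with allele-resolved totals above ``min_total`` in more than
    ``min_cell_frac`` of cells (both inequalities strict).

    ``min_total`` is 6 for the human preset and 10 for the mouse preset.
    """
    if not counts_a.index.equals(counts_b.index) or not counts_a.columns.equals(
        counts_b.columns
    ):
        raise StructuralError("allele count matrices are not aligned")
    total = counts_a + counts_b
    n_cells = total.shape[1]
    n_ok = (total > min_total).sum(axis=1)
    return total.index[n_ok > min_cell_frac * n_cells]


def allelic_ratios(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, min_total: int = 6
) -> pd.DataFrame:
    """Per-gene per-cell a/(a+b) ratios, NaN where the total is too low.

    Only cells whose total clears the informative threshold contribute; a
    total of zero never yields a ratio.
    """
    total = counts_a + counts_b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = counts_a / total
    return ratio.where(total > min_total)


def _categorize(median: float, scheme: str) -> str:
    if median >= 0.85:
        return "monoallelic_a" if scheme == FIVE_CLASS else "monoallelic"
    if median <= 0.15:
        return "monoallelic_b" if scheme == FIVE_CLASS else "monoallelic"
    if median >= 0.7:
        return "biased_a"
    if median <= 0.3:
        return "biased_b"
    return "biallelic"


def classify_allelic(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    scheme: str = FOUR_CLASS,
    min_total: int = 6,
) -> pd.DataFrame:
    """Median allelic-ratio categories per gene.

    Median >= 0.85 or <= 0.15 is monoallelic (split by side in the 5-class
    scheme); [0.7, 0.85) biased to a; (0.15, 0.3] biased to b; (0.3, 0.7)
    biallelic.  Genes with no informative cell are skipped.
    """
    if scheme not in (FOUR_CLASS, FIVE_CLASS):
        raise ArgumentError(f"unknown scheme {scheme!r}")
    ratios = allelic_ratios(counts_a, counts_b, min_total=min_total)
    med = ratios.median(axis=1)
    n_inf = ratios.notna().sum(axis=1)
    keep = n_inf > 0
    rows = pd.DataFrame(
        {
            "median_ratio": med[keep],
            "n_informative_cells": n_inf[keep],
            "category": [_categorize(m, scheme) for m in med[keep]],
        }
    )
    rows.index.name = "gene"
    return rows


def allelic_rt_fisher(
    states_a: np.ndarray,
    states_b: np.ndarray,
    max_missing_frac: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin two-sided Fisher exact test of allelic RT asynchrony.

    ``states_a`` and ``states_b`` are cells x bins ternary state matrices on
    the same (typically 400-kb) grid.  Bins missing in more than
    ``max_missing_frac`` of cells on either haplotype are excluded.  The
    two-sided p-value follows the minimum-likelihood convention (the sum of
    hypergeometric probabilities not exceeding that of the observed table);
    a table with a degenerate margin yields p = 1.
    """
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    if a.shape != b.shape:
        raise StructuralError("haplotype state matrices differ in shape")
    n_cells, n_bins = a.shape
    miss_a = (a == MISSING).mean(axis=0)
    miss_b = (b == MISSING).mean(axis=0)
    informative = (miss_a <= max_missing_frac) & (miss_b <= max_missing_frac)
    p = np.full(n_bins, np.nan)
    for j in np.flatnonzero(informative):
        ra = int(np.sum(a[:, j] == REPLICATED))
        ua = int(np.sum(a[:, j] == UNREPLICATED))
        rb = int(np.sum(b[:, j] == REPLICATED))
        ub = int(np.sum(b[:, j] == UNREPLICATED))
        p[j] = stats.fisher_exact([[ra, ua], [rb, ub]]).pvalue
    out = pd.DataFrame(
        {
            "informative": informative,
            "p_value": p,
            "significant": informative & (p < alpha),
        }
    )
    out.index.name = "bin"
    return out


def link_ratio_to_rt(
    calls: pd.DataFrame,
    avg_rt_a: np.ndarray,
    avg_rt_b: np.ndarray,
    grid: BinGrid,
    gene_annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene allelic RT difference grouped by expression category.

    For each classified gene (5-class scheme), the mean average-mid-S RT of
    the bins overlapping the gene body is computed per haplotype and the
    difference (a minus b) reported alongside the category.  Genes with no
    informative overlapping bin on either haplotype are dropped.
    """
    needed = {"gene", "chrom", "start", "end"}
    if not needed.issubset(gene_annotation.columns):
        raise ArgumentError(f"annotation needs columns {sorted(needed)}")
    ann = gene_annotation.set_index("gene")
    rows = []
    for gene in calls.index:
        if gene not in ann.index:
            continue
        rec = ann.loc[gene]
        idx = grid.bins_overlapping(rec["chrom"], int(rec["start"]), int(rec["end"]))
        if len(idx) == 0:
            continue
        va = np.asarray(avg_rt_a, dtype=float)[idx]
        vb = np.asarray(avg_rt_b, dtype=float)[idx]
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        if len(va) == 0 or len(vb) == 0:
            continue
        rows.append(
            {
                "gene": gene,
                "category": calls.loc[gene, "category"],
                "rt_a": va.mean(),
                "rt_b": vb.mean(),
                "delta_rt": va.mean() - vb.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["category", "rt_a", "rt_b", "delta_rt"]
    )
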