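"""DNA- and RNA-side quality control for single-cell replication profiling.

Implements the cohort fences (Tukey-style quartile rules), the MAD noise
score on 200-kb windows, the Manhattan-distance outlier screen against
S-phase stage peers, the replication-score range rule, ERCC spike-in
correlation and detection-rate diagnostics, and a combined per-cell QC
report.  All printed inequalities are strict; quartiles use linear
interpolation (numpy's default, R type 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, QCError
from .rtcore import MISSING, REPLICATED, UNREPLICATED

__all__ = [
    "mapping_ratio_fence",
    "mad_score",
    "mad_fences",
    "manhattan_distances",
    "manhattan_outlier_fence",
    "score_range_fence",
    "rna_fences",
    "ercc_correlation",
    "detection_rate_curve",
    "qc_report",
]


def _iqr_fences(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def mapping_ratio_fence(ratios: pd.Series) -> pd.Series:
    """Fail cells whose mapping ratio falls below Q1 - 1.5*IQR (strict)."""
    ratios = pd.Series(ratios, dtype=float)
    if len(ratios) < 4:
        warnings.warn("fewer than 4 cells; quartile fence skipped, all pass")
        return pd.Series(True, index=ratios.index)
    low, _ = _iqr_fences(ratios.to_numpy())
    return ratios >= low  # fail iff ratio < low


def mad_score(window_counts: np.ndarray, min_windows: int = 10) -> float:
    """MAD of per-window log2 ratios to the genome-wide median count.

    ``window_counts`` are read counts on non-overlapping 200-kb windows
    (re-bin upstream with :meth:`BinGrid.coarsen`).  Zero-count windows are
    excluded.  No consistency constant is applied, and the score is
    scale-invariant by construction.
    """
    c = np.asarray(window_counts, dtype=float)
    c = c[c > 0]
    if len(c) < min_windows:
        raise QCError(f"only {len(c)} non-zero windows (< {min_windows})")
    x = np.log2(c / np.median(c))
    return float(np.median(np.abs(x - np.median(x))))


def mad_fences(
    mads: pd.Series,
    phase: str,
    g1_max: float = 0.3,
    mids_range: tuple[float, float] = (0.4, 0.8),
    g1_contaminant_max: float = 0.39,
) -> pd.Series:
    """Phase-specific MAD fences.

    G1 cells fail above ``g1_max``; mid-S cells fail outside the open
    interval ``mids_range`` (a too-low mid-S MAD indicates a cell that is
    not actually replicating heterogeneously); the ``G1_CONTAMINANT``
    variant, used to screen S-phase contaminants out of G1-sorted panels,
    fails above ``g1_contaminant_max``.  All inequalities strict.
    """
    mads = pd.Series(mads, dtype=float)
    if phase == "G1":
        return ~(mads > g1_max)
    if phase == "MID_S":
        lo, hi = mids_range
        return ~((mads < lo) | (mads > hi))
    if phase == "G1_CONTAMINANT":
        return ~(mads > g1_contaminant_max)
    raise ArgumentError(f"unknown phase {phase!r}")


def manhattan_distances(
    profiles: pd.DataFrame,
    scores: pd.Series,
    k_neighbors: int = 4,
) -> pd.Series:
    """Per-bin Manhattan distance to each cell's score-order neighbors.

    Cells are sorted by replication score; each cell is compared with its
    ``k_neighbors`` nearest cells in that order (binary 0/1 state coding,
    missing bins excluded pairwise, normalized by the number of compared
    bins), so a cell inconsistent with its S-phase stage peers stands out.
    The cell's statistic is the median over its neighbor distances: with a
    mean, one aberrant cell would drag its own neighbors over the fence.
    A pair with no mutually valid bin is skipped; a cell with no comparable
    neighbor gets NaN.
    """
    scores = scores.reindex(profiles.index)
    order = sorted(profiles.index, key=lambda c: (scores[c], c))
    mat = profiles.loc[order].to_numpy()
    valid = mat != MISSING
    binary = (mat == REPLICATED).astype(float)
    n = len(order)
    dist = np.full(n, np.nan)
    for i in range(n):
        # neighbors by rank distance in score order, nearest first
        ranks = sorted(range(n), key=lambda j: (abs(j - i), j))
        pair_d = []
        for j in ranks:
            if j == i:
                continue
            if len(pair_d) >= k_neighbors:
                break
            both = valid[i] & valid[j]
            if not both.any():
                continue
            pair_d.append(np.abs(binary[i, both] - binary[j, both]).mean())
        if pair_d:
            dist[i] = float(np.median(pair_d))
    return pd.Series(dist, index=order).reindex(profiles.index)


def manhattan_outlier_fence(
    profiles: pd.DataFrame,
    scores: pd.Series,
    k_neighbors: int = 4,
) -> pd.Series:
    """Fail cells whose neighbor distance exceeds Q3 + 1.5*IQR (strict).

    Cells without any comparable neighbor fail outright.
    """
    if len(profiles) < 6:
        raise ArgumentError("need at least 6 cells for the neighbor fence")
    d = manhattan_distances(profiles, scores, k_neighbors=k_neighbors)
    have = d.notna()
    _, high = _iqr_fences(d[have].to_numpy())
    passed = have & ~(d > high)
    return passed


def score_range_fence(
    scores: pd.Series, low: float = 10.0, high: float = 90.0
) -> pd.Series:
    """Fail cells with replication score below 10% or above 90% (strict)."""
    scores = pd.Series(scores, dtype=float)
    return ~((scores < low) | (scores > high))


def rna_fences(metrics: pd.DataFrame) -> pd.DataFrame:
    """RNA-side cohort fences on unique reads, rRNA and mtRNA fractions.

    ``metrics`` has columns ``unique_reads``, ``rrna_frac``, ``mtrna_frac``.
    Unique reads fail below Q1 - 1.5*IQR; the contamination fractions fail
    above Q3 + 1.5*IQR.  Returns per-metric pass flags plus ``pass_rna``.
    """
    needed = {"unique_reads", "rrna_frac", "mtrna_frac"}
    if not needed.issubset(metrics.columns):
        raise ArgumentError(f"metrics table needs columns {sorted(needed)}")
    out = pd.DataFrame(index=metrics.index)
    if len(metrics) < 4:
        warnings.warn("fewer than 4 cells; RNA fences skipped, all pass")
        for c in ("pass_unique_reads", "pass_rrna", "pass_mtrna", "pass_rna"):
            out[c] = True
        return out
    low, _ = _iqr_fences(metrics["unique_reads"].to_numpy(dtype=float))
    out["pass_unique_reads"] = ~(metrics["unique_reads"] < low)
    for col, name in (("rrna_frac", "pass_rrna"), ("mtrna_frac", "pass_mtrna")):
        _, high = _iqr_fences(metrics[col].to_numpy(dtype=float))
        out[name] = ~(metrics[col] > high)
    out["pass_rna"] = out.all(axis=1)
    return out


@dataclass
class ErccResult:
    r: float
    n_detected: int
    passed: bool
    reason: str | None = None


def ercc_correlation(
    spike_counts: pd.Series,
    expected_concentrations: pd.Series,
    min_detected: int = 5,
    r_threshold: float = 0.8,
) -> ErccResult:
    """Pearson r of log10(count+1) vs log10(expected concentration).

    Pass iff r > 0.8 (strict) with at least ``min_detected`` spike-ins at
    count > 0.
    """
    expected = expected_concentrations.reindex(spike_counts.index)
    detected = spike_counts > 0
    n_det = int(detected.sum())
    if n_det < min_detected:
        return ErccResult(np.nan, n_det, False, f"only {n_det} detected spike-ins")
    x = np.log10(spike_counts.to_numpy(dtype=float) + 1.0)
    y = np.log10(expected.to_numpy(dtype=float))
    r = float(stats.pearsonr(x, y).statistic)
    return ErccResult(r, n_det, r > r_threshold)


def detection_rate_curve(
    expr: pd.DataFrame,
    reference_levels: pd.Series,
    thresholds,
) -> tuple[pd.DataFrame, pd.Series]:
    """Detection fraction of reference features per expression threshold.

    For each threshold t, the fraction of reference features expressed above
    t in the reference that a cell detects above t; means and SDs across
    cells, plus the per-cell number of features with TPM > 1.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ArgumentError("thresholds must be ascending")
    ref = reference_levels.dropna()
    if len(ref) == 0:
        raise ArgumentError("empty reference set")
    common = expr.index.intersection(ref.index)
    sub = expr.loc[common].to_numpy(dtype=float)
    refv = ref.loc[common].to_numpy(dtype=float)
    rows = []
    for t in thresholds:
        in_ref = refv > t
        if in_ref.sum() == 0:
            rows.append((t, 0, np.nan, np.nan))
            continue
        frac = (sub[in_ref] > t).mean(axis=0)
        rows.append((t, int(in_ref.sum()), float(frac.mean()), float(frac.std())))
    curve = pd.DataFrame(
        rows, columns=["threshold", "n_reference", "mean_fraction", "sd_fraction"]
    )
    n_tpm1 = (expr > 1).sum(axis=0)
    return curve, n_tpm1


_RULE_ORDER = [
    "pass_mapping_ratio",
    "pass_mad",
    "pass_manhattan",
    "pass_score_range",
    "pass_unique_reads",
    "pass_rrna",
    "pass_mtrna",
    "pass_ercc",
]


def qc_report(flags: pd.DataFrame, metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combine per-rule pass flags into one report.

    ``overall_pass`` is the conjunction of all supplied flags; excluded
    cells carry the name of the first failing rule (in the canonical rule
    order, then any extra columns).
    """
    flags = flags.copy()
    ordered = [c for c in _RULE_ORDER if c in flags.columns] + [
        c for c in flags.columns if c not in _RULE_ORDER
    ]
    flags = flags[ordered]
    report = flags.copy()
    report["overall_pass"] = flags.where(flags.notna(), False).astype(bool).all(axis=1)
    first_fail = []
    for _, row in flags.iterrows():
        fails = [c for c in ordered if not bool(row[c])]
        first_fail.append(fails[0] if fails else "")
    report["first_failing_rule"] = first_fail
    if metrics is not None:
        report = metrics.join(report, how="right")
    return report
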