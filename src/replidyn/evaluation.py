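"""End-to-end benchmark runs on synthetic data with known ground truth.

Each function simulates a dataset at the package's default study
conditions, runs the relevant pipeline stages from scratch, and measures
recovery of the planted truth.  The same routines back the acceptance test
suite and the ``scripts/acceptance.py`` reporter, so the numbers asserted
and the numbers reported are computed by one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chisquare, spearmanr

from . import copyexpr, markers, qcfilters, rtcore, simdata
from .simdata import CNVInterval

__all__ = [
    "score_recovery",
    "binarization_accuracy",
    "profile_fidelity",
    "marker_calibration",
    "marker_null_calibration",
    "copy_effect_null",
    "copy_effect_power",
    "cnv_recovery",
    "downsampling_check",
    "qc_planted_violations",
]


def _decode_cell(ref, f, g1_pool, seed):
    st = simdata.simulate_sphase_states(ref, f, seed=seed)
    counts, _ = simdata.simulate_bin_counts(st, seed=seed + 100_000)
    ratios = rtcore.correct_mappability(counts, g1_pool, ref.grid)
    res = rtcore.binarize_hmm(ratios)
    return st, res


def _reference_and_pool(seed, n_bins=2000, n_domains=40, n_g1=20):
    ref = simdata.make_reference_rt(n_bins, n_domains, seed=seed)
    g1, _ = simdata.simulate_g1_panel(ref, n_cells=n_g1, seed=seed + 1, ploidy=1)
    return ref, g1.sum(axis=0)


# ---------------------------------------------------------------------------
# replication scores and profiles
# ---------------------------------------------------------------------------

def score_recovery(seed: int, n_cells: int = 60, tol_points: float = 3.0) -> dict:
    """Fraction of cells whose decoded replication score is within
    ``tol_points`` percentage points of 100x the true replication fraction."""
    rng = np.random.default_rng(seed)
    ref, pool = _reference_and_pool(seed)
    fractions = rng.uniform(0.15, 0.85, n_cells)
    hits = 0
    errors = []
    for i, f in enumerate(fractions):
        _, res = _decode_cell(ref, f, pool, seed + 10 + i)
        score = rtcore.replication_score(res.states, ref.grid).score
        err = abs(score - 100.0 * f)
        errors.append(err)
        hits += err <= tol_points
    return {
        "fraction_within_tolerance": hits / n_cells,
        "median_abs_error_points": float(np.median(errors)),
        "n": n_cells,
    }


def binarization_accuracy(seed: int, n_cells: int = 10) -> dict:
    """Bin-state agreement with truth for mid-S cells, plus the constant-
    input guard (no spurious replicated calls)."""
    rng = np.random.default_rng(seed)
    ref, pool = _reference_and_pool(seed)
    accs = []
    for i in range(n_cells):
        f = rng.uniform(0.42, 0.68)
        st, res = _decode_cell(ref, f, pool, seed + 500 + i)
        valid = res.states != rtcore.MISSING
        accs.append(float((res.states[valid] == st[valid]).mean()))
    constant = rtcore.binarize_hmm(np.zeros(2000))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "min_accuracy": float(np.min(accs)),
        "spurious_replicated_on_constant": int((constant.states == rtcore.REPLICATED).sum()),
        "n": n_cells,
    }


def profile_fidelity(seed: int, n_cells: int = 22) -> dict:
    """Spearman correlation between the decoded average mid-S profile and
    the generating reference RT profile."""
    rng = np.random.default_rng(seed)
    ref, pool = _reference_and_pool(seed)
    states = []
    scores = []
    for i in range(n_cells):
        f = rng.uniform(0.42, 0.68)
        _, res = _decode_cell(ref, f, pool, seed + 900 + i)
        states.append(res.states)
        scores.append(rtcore.replication_score(res.states, ref.grid).score)
    avg, n_mid = rtcore.average_mid_s(np.array(states), np.array(scores))
    ok = np.isfinite(avg)
    rho = float(spearmanr(avg[ok], ref.rt[ok]).statistic)
    return {"spearman": rho, "n_mid_s_cells": n_mid, "n": n_cells}


# ---------------------------------------------------------------------------
# marker discovery
# ---------------------------------------------------------------------------

def marker_calibration(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 2000,
    n_dynamic: int = 60,
    n_cells: int = 120,
    alpha: float = 0.05,
) -> dict:
    """Pooled empirical FDR and mean sensitivity of dynamic-gene calls.

    Study conditions: ``n_dynamic`` planted genes of ``n_genes`` with
    amplitude 1.5x the noise SD, ``n_cells`` cells, repeated over
    ``n_seeds`` generator seeds; FDR pooled over all calls.
    """
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.15, 0.85, n_cells)
    tp = fp = fn = 0
    sens = []
    for i in range(n_seeds):
        expr, truth = simdata.simulate_expression(
            scores, n_genes=n_genes, n_dynamic=n_dynamic, seed=seed + 31 * i
        )
        tab = markers.fit_dynamic_genes(
            np.log(expr + 1), scores * 100, alpha=alpha, seed=seed + 7 * i
        )
        called = tab["dynamic"].to_numpy()
        true = truth.gene_table["dynamic"].to_numpy()
        tp += int((called & true).sum())
        fp += int((called & ~true).sum())
        fn += int((~called & true).sum())
        sens.append((called & true).sum() / n_dynamic)
    return {
        "empirical_fdr": fp / max(tp + fp, 1),
        "mean_sensitivity": float(np.mean(sens)),
        "n": n_seeds,
    }


def marker_null_calibration(
    seed: int, n_genes: int = 2000, n_cells: int = 120, alpha: float = 0.05
) -> dict:
    """Fraction of genes flagged dynamic on a global-null expression matrix."""
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.15, 0.85, n_cells)
    expr, _ = simdata.simulate_expression(scores, n_genes=n_genes, n_dynamic=0, seed=seed)
    tab = markers.fit_dynamic_genes(np.log(expr + 1), scores * 100, alpha=alpha, seed=seed)
    return {
        "flagged_fraction": float(tab["dynamic"].mean()),
        "raw_p_below_alpha_fraction": float((tab["p_value"] < alpha).mean()),
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# copy-state effect on expression
# ---------------------------------------------------------------------------

def _copy_matrix(rng, n_genes, n_cells):
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    return pd.DataFrame(
        rng.integers(1, 3, size=(n_genes, n_cells)), index=genes, columns=cells
    )


def copy_effect_null(seed: int, n_genes: int = 500, n_cells: int = 80) -> dict:
    """Significant fraction under no copy effect (should sit near alpha)."""
    rng = np.random.default_rng(seed)
    cm = _copy_matrix(rng, n_genes, n_cells)
    exon, genebody = simdata.simulate_spliced_unspliced(cm, base_mu=20, effect=0.0, seed=seed)
    u = copyexpr.unspliced_counts(genebody, exon)
    _, summary = copyexpr.copy_effect_test(exon, u, cm)
    return {
        "significant_fraction_spliced": summary["spliced"]["frac_significant"],
        "significant_fraction_unspliced": summary["unspliced"]["frac_significant"],
        "n": n_genes,
    }


def copy_effect_power(seed: int, n_genes: int = 200, cells_per_group: int = 40) -> dict:
    """Detection power for a two-fold copy effect at base_mu = 20."""
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(2 * cells_per_group)]
    cm = pd.DataFrame(
        np.tile([1] * cells_per_group + [2] * cells_per_group, (n_genes, 1)),
        index=genes, columns=cells,
    )
    exon, genebody = simdata.simulate_spliced_unspliced(cm, base_mu=20, effect=1.0, seed=seed)
    u = copyexpr.unspliced_counts(genebody, exon)
    _, summary = copyexpr.copy_effect_test(exon, u, cm)
    return {
        "power_spliced": summary["spliced"]["frac_significant"],
        "fraction_higher_in_2copy": summary["spliced"]["frac_higher_in_2copy"],
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# CNV recovery
# ---------------------------------------------------------------------------

def cnv_recovery(seed: int, n_cells: int = 100) -> dict:
    """Recovery of an injected 30-Mb 3-copy event (600 50-kb bins).

    Reports the fraction of cells in which the event is called as a single
    copy-3 segment, the fraction with both breakpoints within +-2 bins, the
    number of extra segments on flat control cells, and whether one cell's
    event is found at all four bin sizes.
    """
    from .cnvseg import segment_copy_number

    ref = simdata.make_reference_rt(6000, 1, seed=seed, bin_width=50_000, n_chroms=4)
    panel, _ = simdata.simulate_g1_panel(ref, n_cells=50, seed=seed + 1, ploidy=2)
    g1 = panel.sum(axis=0)
    event = [CNVInterval(300, 900, 3)]

    detected = 0
    precise = 0
    for i in range(n_cells):
        counts, _ = simdata.simulate_g1_panel(
            ref, n_cells=1, cnv_list=event, seed=seed + 10 + i, ploidy=2
        )
        seg = segment_copy_number(counts[0], g1, ref.grid, ploidy=2)
        ev = seg[seg["copy"] == 3]
        if len(ev) == 1 and (seg["copy"] != 2).sum() == 1:
            detected += 1
            if (
                abs(int(ev["start_bin"].iloc[0]) - 300) <= 2
                and abs(int(ev["end_bin"].iloc[0]) - 900) <= 2
            ):
                precise += 1

    extra_segments = 0
    for i in range(n_cells):
        counts, _ = simdata.simulate_g1_panel(
            ref, n_cells=1, seed=seed + 5000 + i, ploidy=2
        )
        seg = segment_copy_number(counts[0], g1, ref.grid, ploidy=2)
        extra_segments += len(seg) - len(ref.grid.chroms)

    counts, _ = simdata.simulate_g1_panel(
        ref, n_cells=1, cnv_list=event, seed=seed + 9999, ploidy=2
    )
    sizes_hit = 0
    for factor in (1, 2, 4, 10):
        grid_c, group = ref.grid.coarsen(factor)
        cc = np.bincount(group, weights=counts[0]).astype(np.int64)
        gg = np.bincount(group, weights=g1).astype(np.int64)
        seg = segment_copy_number(cc, gg, grid_c, ploidy=2)
        sizes_hit += int((seg["copy"] == 3).sum() == 1)

    return {
        "detection_fraction": detected / n_cells,
        "breakpoints_within_2bins_fraction": precise / n_cells,
        "extra_segments_on_flat_cells": extra_segments,
        "bin_sizes_detecting_event": sizes_hit,
        "n": n_cells,
    }


# ---------------------------------------------------------------------------
# downsampling and QC
# ---------------------------------------------------------------------------

def downsampling_check(seed: int, n_genes: int = 1000, target: int = 1_000_000) -> dict:
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        {f"c{j}": rng.integers(500, 5000, n_genes) for j in range(3)}
    )
    out, flags = copyexpr.downsample_library(counts, target=target, seed=seed)
    totals = out.sum()
    expected = counts["c0"] / counts["c0"].sum() * target
    gof = chisquare(out["c0"], expected)
    return {
        "max_total_deviation": int((totals - target).abs().max()),
        "gof_p_value": float(gof.pvalue),
        "n": n_genes,
    }


def qc_planted_violations(seed: int = 0) -> dict:
    """A cohort with one planted violation per QC rule.

    Returns the number of planted cells excluded (expected: all five), the
    number of clean cells excluded (expected: zero), and whether the
    boundary cells (mid-S MAD exactly 0.4, score exactly 10, unique reads
    exactly at the fence) pass per the strict-inequality conventions.
    """
    rng = np.random.default_rng(seed)
    n = 20
    cells = [f"c{i:02d}" for i in range(n)]
    jitter = np.linspace(-1, 1, n)

    mapping = pd.Series(0.55 + 0.01 * jitter, index=cells)
    mapping["c01"] = 0.05                     # planted mapping-ratio violation

    mads = pd.Series(0.55 + 0.02 * jitter, index=cells)
    mads["c02"] = 0.95                        # planted mid-S MAD violation
    mads["c03"] = 0.4                         # boundary: passes (strict <)

    scores = pd.Series(np.linspace(41, 69, n), index=cells)
    scores["c04"] = 95.0                      # planted score-range violation
    scores["c05"] = 10.0                      # boundary: passes (strict <)

    base = rng.choice([1, 2], 150)
    profiles = {}
    for i, c in enumerate(cells):
        p = base.copy()
        flip = rng.choice(150, 2, replace=False)
        p[flip] = 3 - p[flip]
        profiles[c] = p
    profiles["c06"] = 3 - base                # planted inverted profile
    profiles = pd.DataFrame(profiles).T.astype(np.int8)

    rna = pd.DataFrame(
        {
            "unique_reads": 2e6 + 1e4 * jitter,
            "rrna_frac": 0.05 + 0.001 * jitter,
            "mtrna_frac": 0.08 + 0.001 * jitter,
        },
        index=cells,
    )
    rna.loc["c07", "rrna_frac"] = 0.5         # planted rRNA violation
    # boundary: a cell exactly at the unique-reads fence passes
    others = rna["unique_reads"].drop("c08")
    q1, q3 = np.quantile(others, [0.25, 0.75])
    # iterate once: the fence depends on the cohort including the cell
    rna.loc["c08", "unique_reads"] = q1 - 1.5 * (q3 - q1)
    for _ in range(20):
        q1, q3 = np.quantile(rna["unique_reads"], [0.25, 0.75])
        fence = q1 - 1.5 * (q3 - q1)
        if rna.loc["c08", "unique_reads"] == fence:
            break
        rna.loc["c08", "unique_reads"] = fence

    flags = pd.DataFrame(index=cells)
    flags["pass_mapping_ratio"] = qcfilters.mapping_ratio_fence(mapping)
    mid = (scores >= 40) & (scores <= 70)
    mad_ok = qcfilters.mad_fences(mads[mid], "MID_S")
    mad_pass = pd.Series(True, index=cells)
    mad_pass[mad_ok.index[~mad_ok]] = False
    flags["pass_mad"] = mad_pass
    flags["pass_manhattan"] = qcfilters.manhattan_outlier_fence(profiles, scores)
    flags["pass_score_range"] = qcfilters.score_range_fence(scores)
    rnaf = qcfilters.rna_fences(rna)
    flags = flags.join(rnaf[["pass_unique_reads", "pass_rrna", "pass_mtrna"]])
    report = qcfilters.qc_report(flags)

    planted = {"c01", "c02", "c04", "c06", "c07"}
    excluded = set(report.index[~report["overall_pass"]])
    boundary_pass = (
        report.loc["c03", "overall_pass"]
        and report.loc["c05", "overall_pass"]
        and report.loc["c08", "overall_pass"]
    )
    return {
        "planted_excluded": len(planted & excluded),
        "clean_excluded": len(excluded - planted),
        "boundary_cells_pass": bool(boundary_pass),
        "n": n,
    }
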