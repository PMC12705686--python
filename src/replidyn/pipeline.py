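"""End-to-end pipeline: chain simulation, RT profiling, QC and marker
discovery into a reproducible artifact directory.

Each stage writes its outputs plus a JSON provenance record (inputs,
parameters, derived seed, package version); re-running with an identical
config reproduces byte-identical non-log outputs.  Stages communicate only
through files, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, markers, qcfilters, rtcore, simdata
from .config import RunConfig, derive_seed
from .errors import ArgumentError

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "rt", "qc", "markers")

# default problem sizes for the simulated dataset
SIM_N_BINS = 2000
SIM_N_DOMAINS = 40
SIM_N_SCELLS = 40
SIM_N_G1CELLS = 20
SIM_N_GENES = 2000
SIM_N_DYNAMIC = 60


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _provenance(outdir: Path, stage: str, inputs: list[str], params: dict, seed: int):
    io.write_manifest(
        outdir / f"{stage}.provenance.json",
        {
            "stage": stage,
            "inputs": sorted(inputs),
            "parameters": params,
            "seed": seed,
            "version": __version__,
        },
    )


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    seed = derive_seed(config.seed, "simulate")
    rng = np.random.default_rng(seed)
    ref = simdata.make_reference_rt(SIM_N_BINS, SIM_N_DOMAINS, seed=seed)
    fractions = rng.uniform(0.15, 0.85, size=SIM_N_SCELLS)

    cells = [f"cell{i:04d}" for i in range(SIM_N_SCELLS)]
    counts = {}
    truth_states = {}
    for i, cell in enumerate(cells):
        st = simdata.simulate_sphase_states(ref, fractions[i], seed=seed + 1 + i)
        c, _ = simdata.simulate_bin_counts(st, seed=seed + 5000 + i)
        counts[cell] = c
        truth_states[cell] = st
    dna = pd.DataFrame(counts, index=ref.grid.bin_ids())

    g1_counts, _ = simdata.simulate_g1_panel(
        ref, n_cells=SIM_N_G1CELLS, seed=seed + 9000, ploidy=1
    )
    g1_pool = g1_counts.sum(axis=0)

    expr, truth = simdata.simulate_expression(
        fractions, n_genes=SIM_N_GENES, n_dynamic=SIM_N_DYNAMIC, seed=seed + 7
    )
    expr.columns = cells

    ref.grid.to_frame().to_csv(outdir / "grid.tsv", sep="\t", index=False)
    io.write_bedgraph(outdir / "reference_rt.bedgraph", ref.grid, ref.rt)
    io.write_matrix(outdir / "dna_counts.tsv", dna)
    io.write_bincounts(outdir / "g1_pool.tsv", ref.grid, g1_pool)
    io.write_matrix(outdir / "expression_tpm.tsv", expr)
    io.write_matrix(
        outdir / "truth_states.tsv",
        pd.DataFrame(truth_states, index=ref.grid.bin_ids()),
    )
    pd.DataFrame({"cell": cells, "true_fraction": fractions}).to_csv(
        outdir / "truth_fractions.tsv", sep="\t", index=False
    )
    truth.gene_table.to_csv(outdir / "truth_genes.tsv", sep="\t")
    _provenance(
        outdir, "simulate", [],
        {"n_bins": SIM_N_BINS, "n_domains": SIM_N_DOMAINS, "n_cells": SIM_N_SCELLS,
         "n_genes": SIM_N_GENES, "n_dynamic": SIM_N_DYNAMIC}, seed,
    )


def _load_grid(outdir: Path):
    from .grid import BinGrid

    return BinGrid(pd.read_csv(outdir / "grid.tsv", sep="\t"))


def _stage_rt(config: RunConfig, outdir: Path) -> None:
    seed = derive_seed(config.seed, "rt")
    grid = _load_grid(outdir)
    dna = io.read_matrix(outdir / "dna_counts.tsv")
    _, g1_pool = io.read_bincounts(outdir / "g1_pool.tsv")

    states = {}
    scores = {}
    for cell in dna.columns:
        ratios = rtcore.correct_mappability(dna[cell].to_numpy(), g1_pool, grid)
        res = rtcore.binarize_hmm(ratios, expected_mode="S_PHASE")
        states[cell] = res.states
        scores[cell] = rtcore.replication_score(res.states, grid).score
    states_df = pd.DataFrame(states, index=grid.bin_ids()).T  # cells x bins
    scores_s = pd.Series(scores, name="score")

    avg, n_mid = rtcore.average_mid_s(
        states_df.to_numpy(), scores_s.to_numpy(), window=config.mid_s_window
    )
    classes = rtcore.classify_rt(avg)

    io.write_matrix(outdir / "states.tsv", states_df)
    scores_s.rename_axis("cell").to_csv(outdir / "scores.tsv", sep="\t")
    io.write_bedgraph(outdir / "avg_mid_s.bedgraph", grid, avg)
    cls = grid.to_frame()
    cls["rt_class"] = [c if c is not None else "missing" for c in classes.classes]
    cls.to_csv(outdir / "rt_classes.tsv", sep="\t", index=False)
    _provenance(
        outdir, "rt",
        ["dna_counts.tsv", "g1_pool.tsv", "grid.tsv"],
        {"mid_s_window": list(config.mid_s_window), "n_mid_s_cells": n_mid,
         "rt_class_boundaries": [classes.lower3, classes.upper7]}, seed,
    )


def _stage_qc(config: RunConfig, outdir: Path) -> None:
    seed = derive_seed(config.seed, "qc")
    grid = _load_grid(outdir)
    dna = io.read_matrix(outdir / "dna_counts.tsv")
    states = io.read_matrix(outdir / "states.tsv")
    scores = io.read_matrix(outdir / "scores.tsv")["score"]

    factor = max(1, 200_000 // grid.width)
    _, group = grid.coarsen(factor)
    mads = {}
    for cell in dna.columns:
        windowed = np.bincount(group, weights=dna[cell].to_numpy())
        mads[cell] = qcfilters.mad_score(windowed)
    mads = pd.Series(mads)

    flags = pd.DataFrame(index=dna.columns)
    # the mid-S MAD fence applies to cells in the mid-S window; early/late-S
    # cells legitimately sit below it
    mid = (scores >= config.mid_s_window[0]) & (scores <= config.mid_s_window[1])
    mad_ok = qcfilters.mad_fences(mads[mid], "MID_S", mids_range=config.mad_mids_range)
    mad_pass = pd.Series(True, index=dna.columns)
    mad_pass[mad_ok.index[~mad_ok]] = False
    flags["pass_mad"] = mad_pass
    flags["pass_manhattan"] = qcfilters.manhattan_outlier_fence(
        states, scores, k_neighbors=config.manhattan_k_neighbors
    )
    flags["pass_score_range"] = qcfilters.score_range_fence(
        scores, *config.score_range
    )
    report = qcfilters.qc_report(flags, pd.DataFrame({"mad": mads, "score": scores}))
    report.rename_axis("cell").to_csv(outdir / "qc_report.tsv", sep="\t")
    passed = report.index[report["overall_pass"]]
    (outdir / "pass_list.txt").write_text("\n".join(passed) + "\n")
    _provenance(
        outdir, "qc", ["dna_counts.tsv", "states.tsv", "scores.tsv"],
        {"mad_mids_range": list(config.mad_mids_range),
         "score_range": list(config.score_range)}, seed,
    )


def _stage_markers(config: RunConfig, outdir: Path) -> None:
    seed = derive_seed(config.seed, "markers")
    expr = io.read_matrix(outdir / "expression_tpm.tsv")
    scores = io.read_matrix(outdir / "scores.tsv")["score"]
    passed = (outdir / "pass_list.txt").read_text().split()
    cells = [c for c in expr.columns if c in passed]
    expr = expr[cells]
    scores = scores.loc[cells]

    log_expr = np.log(expr + 1.0)
    table = markers.fit_dynamic_genes(
        log_expr, scores.to_numpy(), alpha=config.marker_alpha,
        basis_dim=config.marker_basis_dim,
    )
    expressed = markers.filter_expressed(
        expr, config.marker_min_tpm, config.marker_min_frac
    )
    candidates = table.index[table["dynamic"]].intersection(expressed)
    table["cluster"] = 0
    if len(candidates) >= config.marker_n_clusters:
        order = scores.sort_values(kind="mergesort").index
        labels = markers.cluster_markers(
            log_expr.loc[candidates, order], scores.loc[order].to_numpy(),
            k=config.marker_n_clusters,
        )
        table.loc[candidates, "cluster"] = labels
    table.rename_axis("gene").to_csv(outdir / "dynamic_genes.tsv", sep="\t")
    for lab in sorted(set(table["cluster"]) - {0}):
        genes = table.index[table["cluster"] == lab]
        (outdir / f"cluster{lab}_genes.txt").write_text("\n".join(genes) + "\n")
    _provenance(
        outdir, "markers", ["expression_tpm.tsv", "scores.tsv", "pass_list.txt"],
        {"alpha": config.marker_alpha, "min_tpm": config.marker_min_tpm,
         "min_frac": config.marker_min_frac,
         "n_dynamic": int(table["dynamic"].sum())}, seed,
    )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "rt": _stage_rt,
    "qc": _stage_qc,
    "markers": _stage_markers,
}

_REQUIRES = {
    "simulate": [],
    "rt": ["grid.tsv", "dna_counts.tsv", "g1_pool.tsv"],
    "qc": ["states.tsv", "scores.tsv"],
    "markers": ["expression_tpm.tsv", "scores.tsv", "pass_list.txt"],
}


def run_pipeline(config: RunConfig, stages, outdir) -> Path:
    """Execute the requested stages in dependency order.

    Unknown stage names raise before any computation, as does a missing
    upstream artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ArgumentError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    # check dependencies up front
    will_have = set()
    for s in ordered:
        for artifact in _REQUIRES[s]:
            if s != "simulate" and not (outdir / artifact).exists():
                producers = [t for t in ordered if t in STAGES[: STAGES.index(s)]]
                if not producers:
                    raise ArgumentError(
                        f"stage {s!r} needs {artifact} which no earlier stage produces"
                    )
        will_have.add(s)
    for s in ordered:
        t0 = time.perf_counter()
        _log(f"[replidyn] stage {s} ...")
        _STAGE_FN[s](config, outdir)
        _log(f"[replidyn] stage {s} done in {time.perf_counter() - t0:.1f}s")
    return outdir
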