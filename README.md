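# replidyn

Single-cell replication-timing profiling and S-phase gene-expression
dynamics from binned DNA read counts and matched single-cell RNA data.

## The problem

During S phase a cell duplicates its genome in a reproducible temporal
order: early-replicating regions double their copy number first.
Single-cell whole-genome sequencing of an S-phase cell therefore reads out
a per-bin copy state — 1-copy (unreplicated) or 2-copy (replicated) — and
the fraction of replicated bins gives the cell's position inside S phase, a
pseudotime that needs no marker genes.  When the same cell also yields an
expression profile, one can ask questions that bulk assays cannot answer:
which genes change expression as S phase progresses, whether the two
haplotypes of a locus replicate and transcribe asynchronously together,
and whether doubling a gene's DNA template measurably raises its RNA
output.  The same copy-number readout applied to non-S-phase cells detects
copy-number variants (CNVs).

`replidyn` implements that computational pipeline end to end for people
who have (or simulate) per-cell binned read counts and per-cell expression
matrices: binarization, quality control, S-phase marker discovery,
allele-specific analysis, copy-state/expression testing, and CNV
segmentation — plus a first-class synthetic-data generator with known
ground truth, so every stage is testable without sequencing data.

## The method

**Binarization.** Per-cell bin counts (default 40-kb bins) are corrected
against a pooled G1 reference: both tracks are scaled to counts-per-million
and the per-bin statistic is `log2((s_i + ε) / (g_i + ε))` with ε = 0.5;
blacklist bins and bins with a weak reference are set missing.  A two-state
Gaussian hidden Markov model (EM-fitted, Viterbi-decoded, sticky
transitions) labels each bin unreplicated or replicated; a sorting-gate
constraint declares cells uniform-baseline when the two emission means are
inseparable or a G1-gated cell decodes majority-replicated.

**Replication score.**  `100 · #replicated / (#replicated + #unreplicated)`
over the analyzed genome (abnormal chromosomes and the X excluded per cell
line).  Cells scoring 40–70% are mid-S; the average mid-S profile per bin
is `2 · (replicated fraction) − 1 ∈ [−1, +1]`, and the nine-fraction rule
splits its range into early (> min + 7/9·range), late (< min + 3/9·range)
and mid RT classes.  A per-chromosome uniformity score
`|#unreplicated − #replicated| / #valid` quantifies how far a chromosome is
through replication.

**S-phase markers.**  Each gene's log expression is fit as a penalized
cubic-spline smooth of the replication score (basis dimension 10,
second-derivative penalty, per-gene GCV).  The smooth term's F-type
statistic is calibrated against its permutation null, p-values are
Benjamini–Hochberg adjusted, and a gene is dynamic when FDR < α and the
smooth model beats the intercept on AIC.  Dynamic, expressed genes (TPM ≥ 1
in ≥ 20% of cells) are Ward-clustered on 1 − Pearson distance into three
temporal shape groups.

**Allelic analysis.**  Genes with enough SNP-containing reads
(a + b > 6 [human] or > 10 [mouse] in more than half the cells) get a
per-cell ratio a/(a+b); the median ratio maps to monoallelic / biased /
biallelic categories.  Per 400-kb bin, a two-sided Fisher exact test on the
replicated/unreplicated counts of the two haplotypes flags allelic RT
asynchrony, and the per-gene allelic RT difference is grouped by expression
category.

**Copy-state effect.**  Libraries are downsampled to exactly 1 M reads
(multivariate hypergeometric), unspliced counts are genebody − exon floored
at zero, genes get a per-cell copy state from the mean of their overlapping
binarized bins, and a two-sided Wilcoxon rank-sum test per gene compares
expression between 1-copy and 2-copy mid-S cells.

**CNV detection.**  Mappability-corrected log2 ratios at 50–500-kb bins are
segmented per chromosome by recursive binary segmentation with a BIC
acceptance rule and breakpoint refinement; integer copy calls round
`ploidy · 2^mean` after median-centering.

## Worked example

```python
import numpy as np
from replidyn import simdata, rtcore, markers

# 80-Mb synthetic genome: 2000 40-kb bins in 40 RT domains
ref = simdata.make_reference_rt(n_bins=2000, n_domains=40, seed=1)

# control G1 pool for mappability correction
g1, _ = simdata.simulate_g1_panel(ref, n_cells=20, seed=2, ploidy=1)
pool = g1.sum(axis=0)

# one mid-S cell: truth is 55% replicated
truth = simdata.simulate_sphase_states(ref, f=0.55, seed=3)
counts, _ = simdata.simulate_bin_counts(truth, seed=3)

ratios = rtcore.correct_mappability(counts, pool, ref.grid)
result = rtcore.binarize_hmm(ratios, expected_mode="S_PHASE")
score = rtcore.replication_score(result.states, ref.grid)

valid = result.states != rtcore.MISSING
agreement = (result.states[valid] == truth[valid]).mean()
print(f"replication score: {score.score:.1f}%  ({score.n_valid_bins} bins)")
print(f"agreement with simulated truth: {100 * agreement:.1f}%")
print(f"uniformity score: {rtcore.uniformity_score(result.states):.3f}")

# expression of 120 cells across S phase; 60 of 2000 genes are dynamic
rng = np.random.default_rng(4)
fractions = rng.uniform(0.15, 0.85, 120)
expr, truth_genes = simdata.simulate_expression(fractions, seed=5)
table = markers.fit_dynamic_genes(np.log(expr + 1), fractions * 100,
                                  alpha=0.05, seed=6)
called = table.index[table["dynamic"]]
true_set = truth_genes.gene_table.index[truth_genes.gene_table["dynamic"]]
print(f"dynamic genes called: {len(called)} "
      f"({len(called.intersection(true_set))} of {len(true_set)} planted)")
```

which prints

```
replication score: 55.9%  (1980 bins)
agreement with simulated truth: 96.9%
uniformity score: 0.117
dynamic genes called: 65 (60 of 60 planted)
```

The decoded score (55.9%) recovers the planted replication fraction (55%),
96.9% of bins match the simulated truth, the low uniformity score marks a
mid-S chromosome, and the marker screen recovers all 60 planted dynamic
genes with 5 false calls (FDR 0.077 at α = 0.05).

A thin CLI mirrors the library — `replidyn run --seed 1 --outdir out/`
chains simulation, binarization, QC and marker discovery into an artifact
directory with JSON provenance; `replidyn rt binarize|score|average|
classify|uniformity` and `replidyn cnv` operate on bedGraph-like TSV
tracks.

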