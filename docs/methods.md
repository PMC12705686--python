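# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would otherwise have
to reverse-engineer.  No empirical claim is made here that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All genomic coordinates are 0-based half-open, everywhere.  Bin grids are
sorted, non-overlapping and of constant width except possibly the last bin
of a chromosome; because of this, interval queries are plain integer
arithmetic (`searchsorted`) rather than interval trees.  Per-bin ternary
replication states are coded `0 = missing`, `1 = unreplicated (1-copy)`,
`2 = replicated (2-copy)`.

## The synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes, with known truth, so recovery is measurable.  It is a model of
the *assay*, not of any particular genome.

**Reference RT profile.**  `n_domains` contiguous blocks with independent
uniform levels, smoothed by a 7-bin moving average and rescaled to span
[−1, +1].  The default study conditions use 40 domains per 2000 40-kb bins
(~2-Mb constant-timing domains, the scale of mammalian replication
domains).  Domain scale matters: with very few, very large domains a
single misassigned domain moves the replication score by many points; with
very many tiny domains the binarization problem becomes artificially hard.

**Per-cell replication states.**  Bin *i* of a cell with replication
fraction *f* replicates independently with probability
`logistic(k · (rt_i − τ))`, with τ solved by bisection (tolerance 1e-6 on
the expected fraction, 200 iterations) so the expected replicated fraction
equals *f*.  The steepness default is `k = 1000`: replication order is
then nearly deterministic given the reference profile, with a stochastic
transition zone ~0.3% of the RT range.  This encodes the empirical fact
that single-cell profiles are highly concordant with the population RT
order.  At low steepness the model produces bins that are independent coin
flips — in particular any domain whose RT level coincides with the cell's
threshold becomes irreducibly random, which no decoder can recover; we
consider that an artifact of the simplified iid model rather than a
feature of real cells, where replication is spatially coherent.  The iid
draw (given τ) is the model's main simplification: real cells replicate
contiguous stretches, so this generator slightly *understates* achievable
binarization accuracy.

**Read counts.**  Negative binomial with mean
`depth · mappability · copy` and size parameter `dispersion` (variance
`μ + μ²/r`; large `r` approaches Poisson).  Defaults `depth = 30`
reads/bin and `r = 5` reproduce both the sequencing depth of the assay
(~2 M mapped reads over ~75k 40-kb bins) and whole-genome-amplification
overdispersion at a level consistent with the MAD-score QC windows (a
simulated G1 cell's 200-kb MAD is ~0.23, inside the < 0.3 acceptance
fence).  Missing bins yield zero counts with a mask flag.

**G1 panels and CNVs.**  Baseline copy is the stated ploidy; CNV intervals
(non-overlapping, half-open in bin units) override it with an absolute
copy number in the targeted cells, scaling the NB mean by `copy/ploidy`.

**Expression.**  Log-scale expression is
`baseline_g + A_g · h_g(score) + N(0, noise_sd)`; TPM is the exponential
renormalized per cell to 1e6.  The three temporal shapes — linear up,
linear down, and a Gaussian bump centered at score 0.5 with width
(SD) 0.15 — are standardized to zero mean and unit SD under uniform(0, 1)
scores, so the amplitude *A* is uniformly the per-cell SD of the dynamic
component regardless of shape.  Defaults: 2000 genes, 60 dynamic,
`noise_sd = 0.5`, `A = 0.75` (1.5× the noise SD), baselines `N(2, 1)` on
the natural-log scale.

**Allele-resolved counts.**  Totals are Poisson with mean
`depth · TPM / 1e6`; the a-allele count is binomial with a class-specific
ratio ρ ∈ {0.95, 0.775, 0.5, 0.225, 0.05} for
monoallelic-a / biased-a / biallelic / biased-b / monoallelic-b.

**Spliced/unspliced counts.**  Exon counts are NB with mean
`base_mu · (1 + β · (copy − 1))`; genebody counts add an independent NB
intron component (default half the exon mean) with the same copy
multiplier, so genebody ≥ exon holds by construction and β = 1 doubles
expression in the 2-copy state.

**What passing tests do and do not show.**  The generator captures
overdispersed counts, mappability bias, missing data, domain-structured
RT, dropout-free log-normal expression and preset allelic ratios.  It does
not capture GC waves, amplification breakpoint artifacts, doublets,
expression dropout, bursting, or SNP-density variation along the genome —
recovery rates on synthetic data are therefore upper bounds with respect
to those artifacts, not estimates of performance on any particular real
dataset.

## Binarization

The 2-state Gaussian HMM runs on the finite log2 ratios only; missing bins
are spliced out, so the transition chain bridges gaps (a domain
interrupted by a blacklist region stays one domain).  Initialization is a
median split (component means/variances from the lower and upper halves),
start probabilities 0.5/0.5, and sticky transitions (0.99 self-transition)
to encode domain persistence; EM runs ≤ 200 iterations to a 1e-6
log-likelihood tolerance with all parameters free.  If EM fails, the cell
falls back to nearest-mean assignment under the initial means, with a
warning.  The state with the lower emission mean is unreplicated.

Two overrides mirror the sorting-gate expectation: if the two fitted
emission means differ by < 0.1 the cell is declared uniform-baseline (for
an S-gated cell this is additionally flagged indeterminate — a very-early
or very-late S cell whose state cannot be resolved from DNA alone); if a
G1-gated cell decodes majority-replicated, the baseline interpretation
wins.  In either case all valid bins are reported unreplicated so no
spurious replicated calls leak downstream.  Both thresholds are
configurable.

Because initialization is quantile-based and EM is deterministic, the
procedure is exactly equivariant under adding a constant to all ratios.

## Scores, profiles, classes

The replication score divides replicated by replicated-plus-unreplicated
bins after removing excluded chromosomes (presets: chr10+X for hTERT-RPE1,
chr8+X for CBMS1 mESC, chr1/15/X for HAP1) and blacklist bins; missing
bins count in neither numerator nor denominator.  The mid-S window
(40–70%, bounds inclusive) selects cells for the average profile, whose
per-bin value is `2·fraction − 1`.  The nine-fraction RT classification
uses strict inequalities at both boundaries, matching the printed `>` and
`<`; a constant profile is a classification error.  The mapping of the
average to [−1, +1] is a convention (the boundary *rule*, not the printed
cutoff values, defines the classes); with it, the haploid-line reference cutoffs
(0.213 / −0.287) round-trip from the corresponding profile min/max.

## Quality control

All quartile fences use linear interpolation (numpy default, R type 7) and
strict inequalities.  The MAD score is the median absolute deviation of
per-200-kb-window log2 ratios to the genome-wide median count, zero-count
windows excluded, **without** the 1.4826 consistency constant — the
thresholds (0.3 G1, 0.4–0.8 mid-S, 0.39 contaminant screen) are
protocol-specific calibrations on the same statistic.  The
Manhattan-distance outlier screen compares each cell with its k = 4
nearest neighbors in replication-score order on mutually valid bins
(0/1 coding, normalized per compared bin) and takes the **median** over
the k pair distances: with a mean, one aberrant cell drags its own
neighbors over the Q3 + 1.5·IQR fence, and a cohort with a single
aberrant cell would lose five.  The mid-S MAD fence applies only to cells
in the mid-S score window; early/late-S cells legitimately sit below the
lower bound.  ERCC spike-in correlation is Pearson on
log10(count+1) vs log10(concentration), pass iff r > 0.8 with ≥ 5
detected spike-ins.

## S-phase marker discovery

Per gene, expression is smoothed on the replication score with a cubic
B-spline basis (dimension 10, equally spaced interior knots over the
observed score range) under an exact second-derivative penalty
(Gauss–Legendre per knot span).  Because all genes share the score vector,
one QR + Demmler–Reinsch eigendecomposition reduces every (gene, λ) fit to
shrinkage factors `1/(1 + λ s_j)` applied to rotated coordinates; the full
genes × λ grid (49 values, 1e-5…1e7) costs one matrix product, and GCV
`n·RSS/(n − edf)²` picks λ per gene.

The smooth-term statistic is
`F = ((RSS₀ − RSS)/edf) / (RSS/(n − 1 − edf))` with `edf = tr(S) − 1`.
Its nominal F(edf, n−1−edf) reference ignores the selection effect of
choosing λ from the data and is anti-conservative (on a global null,
~13% of genes at p < 0.05).  The default calibration therefore compares
each gene's statistic with its pooled permutation null: scores are
shuffled across cells (100 permutations), the entire fit — including GCV
selection — is re-run, and `p = (1 + #{null ≥ F}) / (1 + N)` pooled across
genes.  This is exact under the no-association null (expression
exchangeable across cells), keeps per-gene adaptivity, and costs one
matrix product per permutation.  The parametric reference remains
available (`calibration="parametric"`).  AIC is the Gaussian profile form
`n·log(RSS/n) + 2·(edf + 1)` for both the smooth model and the intercept
model (edf 0), so the comparison is internally consistent; a dynamic call
requires both FDR < α (Benjamini–Hochberg) and an AIC win.

Shape clustering uses Ward linkage (scipy's Ward update on the condensed
1 − Pearson distances, i.e. the Ward.D2 convention applied to these
unsquared distances — linkage conventions differ across packages, so this
is pinned) cut at three clusters; labels are ordered by the mean score at
which member genes peak, making them reproducible across runs.
Zero-variance genes are dropped with a warning and labeled 0.

## Allelic analysis

Per-cell ratios use allele-resolved read counts directly (within a gene
the length factor cancels, so count ratios proxy TPM ratios); only cells
whose a+b total strictly exceeds the informative threshold contribute.
Category boundaries follow the printed mixture of ≥/> exactly; the one
ambiguity — a median of exactly 0.15, which the printed rules assign to
both monoallelic and biased-b — resolves to monoallelic.  The per-bin
asynchrony test is the standard two-sided Fisher exact test
(minimum-likelihood convention, via scipy; verified against an exhaustive
hypergeometric enumeration for all tables with margins ≤ 15), applied only
to bins with ≤ 20% missing cells on both haplotypes; degenerate margins
give p = 1.

## Copy-state effect on expression

Downsampling is multivariate-hypergeometric to exactly the target total
(1 M reads), so proportions are unbiased and the result is deterministic
given the seed; cells below target pass through flagged.  A gene's
per-cell copy state is the mean of its overlapping non-missing binarized
bins (any base-pair overlap counts), binarized at 1.5 with the tie going
to replicated.  The variable-gene filter drops genes whose copy state is
constant in more than 80% of informative mid-S cells, then requires
expression (count > 0) in more than 50% of cells by default; a 20% preset
mirrors the alternative filter, and the discrepancy between the two is
deliberately preserved as configuration rather than resolved.  The
per-gene test is a two-sided Wilcoxon rank-sum, exact when both groups are
≤ 25 without ties, else normal approximation with tie and continuity
corrections (verified against full label enumeration for group sizes ≤ 8);
direction is by group medians, with equal medians reported as `equal` and
never significant.

## CNV segmentation

Log2 ratios against the merged-G1 reference are median-centered before
copy calling: the genome-wide median bin anchors the stated ploidy.
Centering removes two biases that otherwise corrupt integer calls — the
CPM shift a large CNV induces on every other bin, and the Jensen gap
between the mean of log ratios and the log of the mean ratio
(≈ −CV²/(2·ln2) ≈ −0.17 at default noise).  Segmentation is recursive
binary splitting per chromosome: each candidate breakpoint maximizes the
between-segment sum-of-squares reduction (computed in O(n) with cumulative
sums) and is accepted iff `n·log(RSS₀/RSS₁) > penalty·log(n)`.  The
penalty multiplier (default 4) is deliberately stiffer than plain BIC
(penalty 1): the split statistic is a maximum over ~n candidate positions,
whose null size grows like 2·log n, so plain BIC produces false
breakpoints on flat cells.  Minimum segment length is 10 bins (guards WGA
spikes).  A refinement pass re-optimizes each accepted breakpoint between
its neighbors, which matters when two true breakpoints fall in one
segment.  Copy = `round(ploidy · 2^mean)` floored at 0.

**Breakpoint precision is data-limited.**  At the default noise (30
reads/bin, NB size 5) the per-bin log2 SD is ≈ 0.7 against a copy-2→3
shift of log2(1.5) = 0.585.  The error distribution of *any* change-point
estimator at this signal-to-noise places roughly half the breakpoints
within ±2 bins (we measured ~55% for an oracle NB-likelihood MLE given the
true segment means); a ±2-bin-in-95%-of-cells requirement at 50-kb bins is
therefore beyond the information in the data, and the corresponding
assertion in the acceptance suite fails by design rather than being
weakened.  Event *detection* (single copy-3 call, correct flanks, all four
bin sizes, no false segments on flat cells) is at 100% in the same runs.

## Problem sizes

The default test and benchmark runs use 2000-bin genomes (80 Mb at 40 kb),
20-cell G1 pools, 60-cell S-phase panels, 2000-gene expression matrices
over 120 cells (20 repetitions for the marker calibration), 500/200-gene
copy-effect panels at 80 cells, and 100-cell CNV panels on 6000-bin
(300 Mb) genomes.  These sizes give binomial standard errors comfortably
inside the asserted margins while keeping the full suite and the benchmark
script fast; all of them are parameters, not constants.

## Known limitations

* The HMM is fit per cell with no information sharing across cells; very
  early/very late S-phase cells with almost-uniform profiles are flagged
  indeterminate rather than rescued (marker-based staging is the natural
  complement, and is out of scope here).
* The permutation calibration assumes cells are exchangeable under the
  null; strong batch structure correlated with the score would violate it.
* Copy calling assumes the median bin sits at the stated ploidy; a genome
  more than half covered by CNVs breaks the anchor.
* The generator's iid-given-threshold replication model understates the
  spatial coherence of real replication, and its expression model has no
  dropout; see the generator section for the full list.
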