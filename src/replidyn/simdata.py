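"""Synthetic single-cell DNA/RNA data with known ground truth.

The generators emulate the statistical structure that the downstream
analysis assumes, so every pipeline stage can be exercised against a known
answer:

* a piecewise-smooth reference replication-timing (RT) profile over a bin
  grid, scaled to [-1, +1] (early = high);
* S-phase cells whose per-bin copy state (1 = unreplicated, 2 = replicated)
  follows that profile through a logistic replication-order model with a
  per-cell replication fraction;
* negative-binomial whole-genome-amplification read counts with a per-bin
  mappability factor (defaults: 30 reads/bin, NB size 5);
* G1-like control panels with optional injected CNV segments;
* expression matrices in which a subset of genes varies smoothly
  (up / down / transient) with the replication score;
* allele-resolved read counts drawn around preset allelic ratios;
* spliced (exon) and unspliced-inclusive (genebody) counts with an optional
  copy-number effect.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ArgumentError, NumericError
from .grid import BinGrid

__all__ = [
    "ReferenceRTProfile",
    "SimTruth",
    "CNVInterval",
    "make_reference_rt",
    "simulate_sphase_states",
    "simulate_bin_counts",
    "simulate_g1_panel",
    "simulate_expression",
    "simulate_allelic_counts",
    "simulate_spliced_unspliced",
    "ALLELIC_RHO",
]

UNREPLICATED = 1
REPLICATED = 2
MISSING = 0

#: default haplotype-a expression fractions for the five allelic classes
ALLELIC_RHO = {
    "monoallelic_a": 0.95,
    "biased_a": 0.775,
    "biallelic": 0.5,
    "biased_b": 0.225,
    "monoallelic_b": 0.05,
}


@dataclass
class ReferenceRTProfile:
    """Continuous reference RT signal on a bin grid (early = high)."""

    grid: BinGrid
    rt: np.ndarray
    domain_labels: np.ndarray | None = None

    def __post_init__(self):
        if len(self.rt) != len(self.grid):
            raise ArgumentError("rt vector does not match bin grid")
        if not np.all(np.isfinite(self.rt)):
            raise ArgumentError("rt values must be finite")


@dataclass
class CNVInterval:
    """Half-open bin-index interval carrying an absolute copy number."""

    start_bin: int
    end_bin: int
    copy: int
    cells: list[int] | None = None  # None = all cells


@dataclass
class SimTruth:
    """Ground-truth carrier for a simulated dataset."""

    fractions: np.ndarray | None = None          # per-cell replication fraction
    states: np.ndarray | None = None             # cells x bins true copy state
    gene_table: pd.DataFrame | None = None       # dynamic flag / shape / amplitude
    allelic_class: pd.Series | None = None       # per-gene class label
    copy_effect: pd.Series | None = None         # per-gene multiplier
    cnvs: list[CNVInterval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference RT profile
# ---------------------------------------------------------------------------

def make_reference_rt(
    n_bins: int,
    n_domains: int,
    seed: int,
    *,
    bin_width: int = 40_000,
    n_chroms: int = 1,
    smooth_halfwidth: int = 3,
    chrom_prefix: str = "chr",
) -> ReferenceRTProfile:
    """Piecewise-constant RT domains, smoothed at boundaries, on [-1, +1].

    Domains partition the genome into contiguous blocks with independent
    uniform levels; a short moving average rounds the boundaries so the
    profile is piecewise-smooth.  The result is rescaled to span exactly
    [-1, +1] unless it is constant (a single domain is allowed and left
    as-is).
    """
    if n_bins <= 0 or n_domains <= 0:
        raise ArgumentError("n_bins and n_domains must be positive")
    if n_bins < n_domains:
        raise ArgumentError("need at least one bin per domain")
    if n_chroms < 1 or n_chroms > n_bins:
        raise ArgumentError("invalid n_chroms")
    rng = np.random.default_rng(seed)

    # domain boundaries: random but at least one bin per domain
    if n_domains == 1:
        bounds = np.array([0, n_bins])
    else:
        cuts = np.sort(rng.choice(np.arange(1, n_bins), size=n_domains - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [n_bins]])
    levels = rng.uniform(-1.0, 1.0, size=n_domains)
    labels = np.empty(n_bins, dtype=np.int64)
    rt = np.empty(n_bins, dtype=float)
    for d in range(n_domains):
        sl = slice(bounds[d], bounds[d + 1])
        rt[sl] = levels[d]
        labels[sl] = d

    if smooth_halfwidth > 0 and n_bins > 2 * smooth_halfwidth:
        w = 2 * smooth_halfwidth + 1
        kernel = np.ones(w) / w
        padded = np.pad(rt, smooth_halfwidth, mode="edge")
        rt = np.convolve(padded, kernel, mode="valid")

    span = rt.max() - rt.min()
    if span > 1e-12:
        rt = 2.0 * (rt - rt.min()) / span - 1.0

    # split evenly into synthetic chromosomes
    per = int(np.ceil(n_bins / n_chroms))
    sizes = {}
    for i in range(n_chroms):
        n_here = min(per, n_bins - i * per)
        if n_here <= 0:
            break
        sizes[f"{chrom_prefix}{i + 1}"] = n_here * bin_width
    grid = BinGrid.from_chrom_sizes(sizes, bin_width)
    return ReferenceRTProfile(grid=grid, rt=rt, domain_labels=labels)


# ---------------------------------------------------------------------------
# S-phase copy states
# ---------------------------------------------------------------------------

def _solve_threshold(rt: np.ndarray, f: float, k: float, tol: float = 1e-6,
                     max_iter: int = 200) -> float:
    """Bisection for the logistic threshold tau with E[replicated] = f."""
    lo, hi = rt.min() - 1.0, rt.max() + 1.0

    def expected(tau):
        return float(np.mean(expit(k * (rt - tau))))

    # expected fraction decreases in tau
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        e = expected(mid)
        if abs(e - f) < tol:
            return mid
        if e > f:
            lo = mid
        else:
            hi = mid
    raise NumericError(
        f"threshold bisection did not reach |E[frac]-f| < {tol} in {max_iter} iterations"
    )


def simulate_sphase_states(
    ref: ReferenceRTProfile, f: float, k: float = 1000.0, seed: int = 0
) -> np.ndarray:
    """Per-bin true copy states for one S-phase cell.

    Bin *i* replicates with probability ``logistic(k * (rt_i - tau))`` where
    ``tau`` is solved so the expected replicated fraction equals ``f``:
    early-RT bins replicate first, and the steepness ``k`` sets how strictly
    the cell follows the reference order.
    """
    if not 0.0 < f < 1.0:
        raise ArgumentError("replication fraction f must be in (0, 1)")
    if k <= 0:
        raise ArgumentError("steepness k must be positive")
    rng = np.random.default_rng(seed)
    tau = _solve_threshold(ref.rt, f, k)
    p = expit(k * (ref.rt - tau))
    replicated = rng.random(len(p)) < p
    return np.where(replicated, REPLICATED, UNREPLICATED).astype(np.int8)


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with mean ``mean`` and size (dispersion) parameter r.

    var = mu + mu^2 / r, so r -> inf approaches Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        r = float(dispersion)
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_bin_counts(
    states: np.ndarray,
    depth_per_bin: float = 30.0,
    dispersion: float = 5.0,
    mappability: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial read counts for one cell given true copy states.

    Returns ``(counts, masked)`` where ``masked`` flags bins whose state is
    MISSING (those get count 0).
    """
    if depth_per_bin <= 0 or dispersion <= 0:
        raise ArgumentError("depth and dispersion must be positive")
    states = np.asarray(states)
    n = len(states)
    if mappability is None:
        mappability = np.ones(n)
    mappability = np.asarray(mappability, dtype=float)
    if len(mappability) != n:
        raise ArgumentError("mappability vector does not match bins")
    rng = np.random.default_rng(seed)
    copy = states.astype(float)
    masked = states == MISSING
    mean = depth_per_bin * mappability * copy
    mean[masked] = 0.0
    counts = _nb_draw(rng, mean, dispersion)
    return counts, masked


def simulate_g1_panel(
    ref: ReferenceRTProfile,
    n_cells: int = 100,
    depth: float = 30.0,
    dispersion: float = 5.0,
    mappability: np.ndarray | None = None,
    cnv_list: list[CNVInterval] | None = None,
    seed: int = 0,
    ploidy: int = 2,
) -> tuple[np.ndarray, SimTruth]:
    """Counts for a panel of non-S-phase cells with optional injected CNVs.

    Baseline copy number is ``ploidy`` everywhere; each CNV interval replaces
    it by the interval's absolute copy number in the targeted cells (all
    cells by default).  The per-bin mean is ``depth * mappability * copy /
    ploidy`` so baseline bins average ``depth`` reads.
    """
    if n_cells <= 0:
        raise ArgumentError("n_cells must be positive")
    n_bins = len(ref.grid)
    cnv_list = list(cnv_list or [])
    # validate: inside grid and pairwise non-overlapping
    ivs = sorted((c.start_bin, c.end_bin) for c in cnv_list)
    for s, e in ivs:
        if not (0 <= s < e <= n_bins):
            raise ArgumentError(f"CNV interval [{s}, {e}) outside the grid")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ArgumentError("overlapping CNV intervals")
    if mappability is None:
        mappability = np.ones(n_bins)
    rng = np.random.default_rng(seed)
    copy = np.full((n_cells, n_bins), float(ploidy))
    for c in cnv_list:
        rows = range(n_cells) if c.cells is None else c.cells
        for r in rows:
            copy[r, c.start_bin : c.end_bin] = c.copy
    mean = depth * mappability[None, :] * copy / float(ploidy)
    counts = _nb_draw(rng, mean, dispersion)
    truth = SimTruth(states=copy.astype(np.int8), cnvs=cnv_list)
    return counts, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_SHAPES = ("increasing", "decreasing", "transient")


# the Gaussian bump's mean and SD under uniform(0, 1) scores, so all shape
# functions share zero mean and unit SD and the amplitude is uniformly the
# per-cell SD of the dynamic component
_BUMP_MEAN = 0.3757
_BUMP_SD = 0.3532


def _shape_fn(name: str, s: np.ndarray) -> np.ndarray:
    """Temporal shape functions, standardized under uniform scores."""
    if name == "increasing":
        return np.sqrt(12.0) * (s - 0.5)
    if name == "decreasing":
        return np.sqrt(12.0) * (0.5 - s)
    if name == "transient":
        bump = np.exp(-((s - 0.5) ** 2) / (2 * 0.15**2))
        return (bump - _BUMP_MEAN) / _BUMP_SD
    raise ArgumentError(f"unknown shape {name!r}")


def simulate_expression(
    scores: np.ndarray,
    n_genes: int = 2000,
    n_dynamic: int = 60,
    shapes: tuple[str, ...] = _SHAPES,
    amplitude: float = 0.75,
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline_mean: float = 2.0,
    baseline_sd: float = 1.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Genes x cells TPM matrix with a planted set of S-phase dynamic genes.

    Log-scale expression is ``baseline_g + A_g * h_g(score) + N(0, noise_sd)``
    with h linear-up, linear-down or a unit-height Gaussian bump centred at
    score 0.5 (width 0.15).  Non-dynamic genes have A = 0.  TPM is the
    exponential, renormalized per cell to 1e6.  The default amplitude is
    1.5x the noise SD.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any((scores <= 0) | (scores >= 1)):
        raise ArgumentError("scores must be strictly inside (0, 1)")
    if n_dynamic > n_genes:
        raise ArgumentError("n_dynamic exceeds n_genes")
    rng = np.random.default_rng(seed)
    n_cells = len(scores)
    genes = pd.Index([f"gene{i:05d}" for i in range(n_genes)])
    cells = pd.Index([f"cell{j:04d}" for j in range(n_cells)])

    dynamic_idx = rng.choice(n_genes, size=n_dynamic, replace=False)
    shape_of = np.array([""] * n_genes, dtype=object)
    amp = np.zeros(n_genes)
    for j, g in enumerate(dynamic_idx):
        shape_of[g] = shapes[j % len(shapes)]
        amp[g] = amplitude

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    log_expr = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_cells))
    for g in dynamic_idx:
        log_expr[g] += amp[g] * _shape_fn(shape_of[g], scores)

    raw = np.exp(log_expr)
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    expr = pd.DataFrame(tpm, index=genes, columns=cells)
    table = pd.DataFrame(
        {
            "dynamic": np.isin(np.arange(n_genes), dynamic_idx),
            "shape": shape_of,
            "amplitude": amp,
        },
        index=genes,
    )
    return expr, SimTruth(fractions=scores.copy(), gene_table=table)


def simulate_allelic_counts(
    expr_tpm: pd.DataFrame,
    class_per_gene: pd.Series,
    depth: float = 100_000.0,
    seed: int = 0,
    rho: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-resolved (SNP-containing) read counts per gene and cell.

    Total counts are Poisson with mean ``depth * TPM / 1e6``; the
    haplotype-a count is binomial with the class-specific ratio.
    """
    rho = dict(ALLELIC_RHO if rho is None else rho)
    missing = set(class_per_gene.unique()) - set(rho)
    if missing:
        raise ArgumentError(f"no ratio preset for classes {sorted(missing)}")
    class_per_gene = class_per_gene.reindex(expr_tpm.index)
    if class_per_gene.isna().any():
        raise ArgumentError("class_per_gene must cover every gene in expr_tpm")
    rng = np.random.default_rng(seed)
    mean = depth * expr_tpm.to_numpy() / 1e6
    total = rng.poisson(mean)
    p = class_per_gene.map(rho).to_numpy(dtype=float)[:, None]
    count_a = rng.binomial(total, np.broadcast_to(p, total.shape))
    count_b = total - count_a
    a = pd.DataFrame(count_a, index=expr_tpm.index, columns=expr_tpm.columns)
    b = pd.DataFrame(count_b, index=expr_tpm.index, columns=expr_tpm.columns)
    return a, b


def simulate_spliced_unspliced(
    copy_state: pd.DataFrame,
    base_mu: float = 20.0,
    effect: float = 0.0,
    dispersion: float = 5.0,
    intron_frac: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon and genebody counts with an optional copy-number effect.

    ``copy_state`` holds per-gene per-cell states in {1, 2}.  Exon counts are
    NB with mean ``base_mu * (1 + effect * (copy - 1))``; genebody counts add
    an independent NB intron component with the same copy multiplier, so
    genebody >= exon by construction.
    """
    states = copy_state.to_numpy()
    if not np.isin(states, (1, 2)).all():
        raise ArgumentError("copy states must be 1 or 2")
    if effect < 0:
        raise ArgumentError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    mult = 1.0 + effect * (states - 1.0)
    exon = _nb_draw(rng, base_mu * mult, dispersion)
    intron = _nb_draw(rng, intron_frac * base_mu * mult, dispersion)
    genebody = exon + intron
    idx, cols = copy_state.index, copy_state.columns
    return (
        pd.DataFrame(exon, index=idx, columns=cols),
        pd.DataFrame(genebody, index=idx, columns=cols),
    )
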