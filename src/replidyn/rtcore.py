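"""Core single-cell replication-timing computations.

From per-cell binned DNA read counts to:

* mappability-corrected log2 ratios against a pooled G1 reference,
* binarized replication states via a two-state Gaussian HMM
  (1-copy = unreplicated, 2-copy = replicated),
* percentage replication scores (the S-phase pseudotime axis),
* average mid-S RT profiles on the [-1, +1] scale,
* early/mid/late RT classes by the nine-fraction rule,
* per-chromosome replication uniformity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, QCError, StructuralError
from .grid import BinGrid

__all__ = [
    "MISSING",
    "UNREPLICATED",
    "REPLICATED",
    "BinarizationResult",
    "ReplicationScore",
    "RTClassTable",
    "correct_mappability",
    "binarize_hmm",
    "replication_score",
    "average_mid_s",
    "classify_rt",
    "uniformity_score",
    "sort_and_stack",
]

MISSING = 0
UNREPLICATED = 1  # 1-copy
REPLICATED = 2    # 2-copy


# ---------------------------------------------------------------------------
# mappability correction
# ---------------------------------------------------------------------------

def correct_mappability(
    cell_counts: np.ndarray,
    g1_pool_counts: np.ndarray,
    grid: BinGrid | None = None,
    blacklist: pd.DataFrame | None = None,
    eps: float = 0.5,
    g1_floor_quantile: float = 0.01,
) -> np.ndarray:
    """Per-bin log2 ratio of a cell against the summed G1 control pool.

    Both count vectors are scaled to counts-per-million over non-blacklist
    bins, then ``log2((s + eps) / (g + eps))`` with a pseudo-count guarding
    zero bins.  Bins in the blacklist, or whose G1 pool count falls below the
    floor (default: the bottom 1% quantile), are returned as NaN (missing).
    """
    s = np.asarray(cell_counts, dtype=float)
    g = np.asarray(g1_pool_counts, dtype=float)
    if s.shape != g.shape:
        raise StructuralError("cell and G1 pool counts are on different grids")
    if grid is not None and len(grid) != len(s):
        raise StructuralError("counts do not match the bin grid")
    if g.sum() <= 0:
        raise ArgumentError("empty G1 pool")

    bl = np.zeros(len(s), dtype=bool)
    if blacklist is not None:
        if grid is None:
            raise ArgumentError("a grid is required to apply a blacklist")
        bl = grid.region_mask(blacklist)

    keep = ~bl
    s_cpm = s / max(s[keep].sum(), 1.0) * 1e6
    g_cpm = g / max(g[keep].sum(), 1.0) * 1e6

    floor = np.quantile(g[keep], g1_floor_quantile)
    missing = bl | (g < floor) | (g <= 0)

    ratio = np.log2((s_cpm + eps) / (g_cpm + eps))
    ratio[missing] = np.nan
    return ratio


# ---------------------------------------------------------------------------
# HMM binarization
# ---------------------------------------------------------------------------

@dataclass
class BinarizationResult:
    """Per-bin ternary replication states plus fit diagnostics."""

    states: np.ndarray                       # int8, {0 missing, 1 unrep, 2 rep}
    uniform_baseline: bool = False
    indeterminate: bool = False
    converged: bool = True
    emission_means: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)


def _two_means_assign(x: np.ndarray, m0: float, m1: float) -> np.ndarray:
    return (np.abs(x - m1) < np.abs(x - m0)).astype(int)


def binarize_hmm(
    log2_ratios: np.ndarray,
    expected_mode: str = "S_PHASE",
    min_bins: int = 100,
    mean_separation: float = 0.1,
    n_iter: int = 200,
    tol: float = 1e-6,
    self_transition: float = 0.99,
) -> BinarizationResult:
    """Binarize a cell's log2 ratio track with a 2-state Gaussian HMM.

    Missing bins (NaN) are skipped: the HMM runs on the concatenated valid
    bins, so the transition chain bridges gaps.  The state with the lower
    emission mean is labeled unreplicated.  A mode constraint mirrors the
    sorting-gate expectation: a cell sorted from the G1 gate whose most
    frequent state is not the 1-copy baseline, or any cell whose two
    emission means are separated by less than ``mean_separation``, is
    declared uniform-baseline (G1) or flagged indeterminate (S phase); in
    either case all valid bins are reported unreplicated so no spurious
    replicated calls are produced.
    """
    if expected_mode not in ("G1_BASELINE", "S_PHASE"):
        raise ArgumentError(f"unknown mode {expected_mode!r}")
    x = np.asarray(log2_ratios, dtype=float)
    valid = np.isfinite(x)
    n_valid = int(valid.sum())
    if n_valid < min_bins:
        raise QCError(f"only {n_valid} non-missing bins (< {min_bins})")
    obs = x[valid]

    states_full = np.zeros(len(x), dtype=np.int8)
    notes: list[str] = []

    med = np.median(obs)
    lower = obs[obs <= med]
    upper = obs[obs > med]
    if len(upper) == 0 or len(lower) == 0 or obs.std() < 1e-12:
        # constant track: nothing to separate
        states_full[valid] = UNREPLICATED
        return BinarizationResult(
            states=states_full,
            uniform_baseline=True,
            indeterminate=expected_mode == "S_PHASE",
            emission_means=(float(med), float(med)),
            warnings=["constant input; uniform-baseline declared"],
        )

    init_means = np.array([[lower.mean()], [upper.mean()]])
    init_vars = np.array(
        [[max(lower.var(), 1e-4)], [max(upper.var(), 1e-4)]]
    )

    import logging

    from hmmlearn.hmm import GaussianHMM

    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        init_params="",
        params="stmc",
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array(
        [[self_transition, 1 - self_transition], [1 - self_transition, self_transition]]
    )
    model.means_ = init_means
    model.covars_ = init_vars

    X = obs.reshape(-1, 1)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
        converged = bool(model.monitor_.converged)
        means = model.means_.ravel()
        _, decoded = model.decode(X, algorithm="viterbi")
    except Exception as exc:  # degenerate EM: fall back to 2-means on the init
        converged = False
        notes.append(f"EM failed ({exc}); 2-means fallback")
        means = init_means.ravel()
        decoded = _two_means_assign(obs, means[0], means[1])
    if not converged and not notes:
        notes.append("EM did not converge; 2-means fallback")
        means = init_means.ravel()
        decoded = _two_means_assign(obs, means[0], means[1])

    # relabel: component with lower emission mean is unreplicated
    if means[0] <= means[1]:
        rep = decoded == 1
        lo_mean, hi_mean = float(means[0]), float(means[1])
    else:
        rep = decoded == 0
        lo_mean, hi_mean = float(means[1]), float(means[0])

    sep = hi_mean - lo_mean
    frac_rep = rep.mean()
    most_frequent_is_baseline = frac_rep <= 0.5

    uniform = False
    indeterminate = False
    if sep < mean_separation:
        uniform = True
        indeterminate = expected_mode == "S_PHASE"
        notes.append(f"emission means separated by {sep:.3g} < {mean_separation}")
    elif expected_mode == "G1_BASELINE" and not most_frequent_is_baseline:
        uniform = True
        notes.append("most frequent state is not the 1-copy baseline; overridden")

    if uniform:
        states_full[valid] = UNREPLICATED
    else:
        states_full[valid] = np.where(rep, REPLICATED, UNREPLICATED)

    return BinarizationResult(
        states=states_full,
        uniform_baseline=uniform,
        indeterminate=indeterminate,
        converged=converged,
        emission_means=(lo_mean, hi_mean),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# replication score
# ---------------------------------------------------------------------------

@dataclass
class ReplicationScore:
    """Percentage of replicated bins over the analyzed genome of one cell."""

    score: float
    n_valid_bins: int
    excluded_chroms: tuple[str, ...] = ()


def replication_score(
    states: np.ndarray,
    grid: BinGrid | None = None,
    exclude_chroms=(),
    blacklist: pd.DataFrame | None = None,
) -> ReplicationScore:
    """100 x (#replicated) / (#replicated + #unreplicated) after exclusions.

    Excluded chromosomes and blacklist bins leave both numerator and
    denominator; so do missing bins.
    """
    states = np.asarray(states)
    keep = np.ones(len(states), dtype=bool)
    if exclude_chroms:
        if grid is None:
            raise ArgumentError("a grid is required to exclude chromosomes")
        keep &= ~grid.chrom_mask(exclude_chroms)
    if blacklist is not None:
        if grid is None:
            raise ArgumentError("a grid is required to apply a blacklist")
        keep &= ~grid.region_mask(blacklist)
    rep = int(np.sum((states == REPLICATED) & keep))
    unrep = int(np.sum((states == UNREPLICATED) & keep))
    total = rep + unrep
    if total == 0:
        raise QCError("no valid bins after exclusions")
    return ReplicationScore(
        score=100.0 * rep / total,
        n_valid_bins=total,
        excluded_chroms=tuple(exclude_chroms),
    )


# ---------------------------------------------------------------------------
# average mid-S profile and RT classes
# ---------------------------------------------------------------------------

def average_mid_s(
    states_matrix: np.ndarray,
    scores: np.ndarray,
    window: tuple[float, float] = (40.0, 70.0),
) -> tuple[np.ndarray, int]:
    """Average RT profile from mid-S cells on the [-1, +1] scale.

    Per bin, ``2 * (#replicated among informative cells) / (#informative)
    - 1``; informative means non-missing.  Bins with no informative cell are
    NaN.  Returns the profile and the number of cells inside the window
    (inclusive bounds).
    """
    states_matrix = np.asarray(states_matrix)
    scores = np.asarray(scores, dtype=float)
    if states_matrix.shape[0] != len(scores):
        raise ArgumentError("one score per cell required")
    lo, hi = window
    sel = (scores >= lo) & (scores <= hi)
    n_cells = int(sel.sum())
    if n_cells == 0:
        raise ArgumentError(f"no cells with scores inside [{lo}, {hi}]")
    sub = states_matrix[sel]
    informative = sub != MISSING
    rep = (sub == REPLICATED).sum(axis=0).astype(float)
    n_inf = informative.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = 2.0 * rep / n_inf - 1.0
    value[n_inf == 0] = np.nan
    return value, n_cells


@dataclass
class RTClassTable:
    """Early/mid/late RT class per bin with the nine-fraction boundaries."""

    classes: np.ndarray  # object array of {'early','mid','late', None}
    lower3: float
    upper7: float


def classify_rt(avg_values: np.ndarray) -> RTClassTable:
    """Nine-fraction RT classes of an average mid-S profile.

    The min-to-max range is divided into nine equal fractions; bins above
    the 7th boundary are early, below the 3rd boundary late, in between mid
    (strict inequalities).  Missing bins propagate.
    """
    v = np.asarray(avg_values, dtype=float)
    finite = np.isfinite(v)
    vals = v[finite]
    if len(np.unique(vals)) < 2:
        raise ArgumentError("constant profile cannot be classified")
    vmin, vmax = vals.min(), vals.max()
    rng = vmax - vmin
    lower3 = vmin + (3.0 / 9.0) * rng
    upper7 = vmin + (7.0 / 9.0) * rng
    classes = np.array([None] * len(v), dtype=object)
    classes[finite & (v > upper7)] = "early"
    classes[finite & (v < lower3)] = "late"
    classes[finite & (v >= lower3) & (v <= upper7)] = "mid"
    return RTClassTable(classes=classes, lower3=float(lower3), upper7=float(upper7))


# ---------------------------------------------------------------------------
# uniformity and stacking
# ---------------------------------------------------------------------------

def uniformity_score(
    states: np.ndarray,
    grid: BinGrid | None = None,
    chrom: str | None = None,
) -> float:
    """|#unreplicated - #replicated| / #valid bins (1 = fully uniform)."""
    states = np.asarray(states)
    if chrom is not None:
        if grid is None:
            raise ArgumentError("a grid is required to select a chromosome")
        states = states[grid.chrom_mask([chrom])]
    u = int(np.sum(states == UNREPLICATED))
    r = int(np.sum(states == REPLICATED))
    if u + r == 0:
        raise QCError("no valid bins")
    return abs(u - r) / (u + r)


def sort_and_stack(profiles: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Order a cells x bins state matrix by ascending replication score.

    Ties are broken by cell id (lexicographic) so the stacking is
    reproducible.
    """
    if profiles.index.duplicated().any():
        raise StructuralError("duplicate cell ids")
    scores = scores.reindex(profiles.index)
    if scores.isna().any():
        raise StructuralError("every cell needs a score")
    order = sorted(profiles.index, key=lambda c: (scores[c], c))
    return profiles.loc[order]
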