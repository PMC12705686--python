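"""Independent brute-force oracles used by the test suites.

These deliberately share no code with the implementations they check: the
Fisher oracle enumerates the full hypergeometric support, and the rank-sum
oracle enumerates every label assignment.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def fisher_two_sided_oracle(table) -> float:
    """Exhaustive minimum-likelihood two-sided Fisher p for a 2x2 table."""
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    N = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or b + d == 0:
        return 1.0
    support = np.arange(max(0, k - n2), min(n1, k) + 1)
    pmf = stats.hypergeom.pmf(support, N, n1, k)
    p_obs = stats.hypergeom.pmf(a, N, n1, k)
    # float-tolerant tie rule: tables as likely as the observed one count
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def exact_ranksum_oracle(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of label assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    all_sums = np.array(
        [ranks[list(c)].sum() for c in combinations(range(len(pooled)), n1)]
    )
    lo = (all_sums <= obs + 1e-9).mean()
    hi = (all_sums >= obs - 1e-9).mean()
    return min(1.0, 2.0 * min(lo, hi))
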