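"""Non-parametric comparison of normalization methods across paired configurations.

Three-stage procedure: an omnibus Friedman rank test over all treatments,
a Nemenyi critical-difference post hoc on mean ranks, and exact Wilcoxon
signed-rank tests for fine-grained pairwise comparisons.

The Wilcoxon p-value is computed from the exact null distribution of the
signed-rank sum (equivalent to full enumeration of all sign assignments)
whenever the number of non-zero differences is at most ``EXACT_LIMIT``;
ties among the absolute differences are handled with midranks, in which case
the enumerated distribution is the permutation distribution conditional on
the observed midranks.  Larger samples use the normal approximation with
tie correction.  Zero differences are discarded (classical treatment, not
Pratt's); ``n_effective`` reports how many pairs remained.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from radnorm.errors import ContractError, InputError

__all__ = [
    "TestResult",
    "ComparisonResult",
    "wilcoxon_signed_rank",
    "friedman",
    "nemenyi_cd",
    "score_matrix",
    "compare_methods",
]

#: Largest n for which the exact signed-rank null distribution is used.
EXACT_LIMIT = 25

# Critical values q_alpha for the Nemenyi test (studentized range statistic
# divided by sqrt(2)), k = 2..10 treatments.  Standard published two-tailed
# values for infinite degrees of freedom.
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920],
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ContractError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ComparisonResult:
    """Full three-stage comparison report."""

    scores: pd.DataFrame  # blocks x treatments
    friedman: TestResult
    mean_ranks: pd.Series
    nemenyi_critical_difference: Optional[float]
    pairwise: pd.DataFrame  # one row per treatment pair
    alpha: float


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Exact null counts of the doubled positive-rank sum.

    ``dist[s]`` = number of sign assignments whose doubled W+ equals ``s``;
    computed by dynamic programming over the rank polynomial, identical to
    enumerating all 2^n sign vectors.
    """
    total = int(double_ranks.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Differences ``d = x - y``; zeros are discarded; |d| is ranked with
    midranks.  The reported statistic is ``W = min(W+, W-)``.  Alternatives:
    ``greater`` means x tends to exceed y (large W+).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ContractError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ContractError("x and y must be equal-length 1-D vectors")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon-degenerate", 0, True)

    ranks = sps.rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if n <= EXACT_LIMIT:
        dr = np.round(2.0 * ranks).astype(int)
        dist = _signed_rank_distribution(dr)
        total = dist.sum()  # 2^n
        wp2 = int(round(2.0 * w_plus))
        wm2 = int(round(2.0 * w_minus))
        if alternative == "greater":
            p = dist[wp2:].sum() / total
        elif alternative == "less":
            p = dist[: wp2 + 1].sum() / total
        else:
            lo2, hi2 = min(wp2, wm2), max(wp2, wm2)
            p = (dist[: lo2 + 1].sum() + dist[hi2:].sum()) / total
        return TestResult(statistic, min(float(p), 1.0), "wilcoxon-exact", n, True)

    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = np.sqrt(var)
    z = (w_plus - mean) / sd
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(statistic, min(float(p), 1.0), "wilcoxon-normal", n, False)


def friedman(scores: pd.DataFrame | np.ndarray) -> TestResult:
    """Friedman rank test over a blocks-by-treatments score matrix.

    Within-block midranks; the tie-corrected statistic

        chi2 = (k-1) * (sum_j R_j^2 - n^2 k (k+1)^2 / 4)
                     / (sum_ij r_ij^2 - n k (k+1)^2 / 4)

    reduces to the classical ``12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)``
    when no ties are present.  The p-value uses the chi-squared distribution
    with k-1 degrees of freedom, an asymptotic reference that is liberal for
    very small n (the exact permutation distribution is not implemented).
    """
    mat = np.asarray(scores, dtype=np.float64)
    if mat.ndim != 2:
        raise ContractError("score matrix must be 2-D (blocks x treatments)")
    n, k = mat.shape
    if k < 2 or n < 2:
        raise ContractError(f"need >=2 treatments and >=2 blocks, got {mat.shape}")
    ranks = np.apply_along_axis(sps.rankdata, 1, mat)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * (np.square(col_sums).sum() - n * n * k * (k + 1) ** 2 / 4.0)
    den = np.square(ranks).sum() - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # every block constant
        return TestResult(0.0, 1.0, "friedman", n, False)
    chi2 = num / den
    p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult(float(chi2), p, "friedman", n, False)


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference ``q_alpha(k) * sqrt(k (k+1) / (6 n))``.

    Two mean ranks differ significantly when their absolute difference is at
    least the returned value.  Supported: 2 <= k <= 10, alpha in {0.05, 0.10}.
    """
    if alpha not in _NEMENYI_Q:
        raise ContractError(f"alpha must be one of {sorted(_NEMENYI_Q)}, got {alpha}")
    if not 2 <= k <= 10:
        raise ContractError(f"k must be in [2, 10] (embedded table bounds), got {k}")
    if n < 1:
        raise ContractError("n must be >= 1")
    q = _NEMENYI_Q[alpha][k - 2]
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def score_matrix(
    results: pd.DataFrame,
    metric: str = "f1",
    treatment: str = "method",
    block_keys: Sequence[str] = ("dataset", "model"),
) -> pd.DataFrame:
    """Pivot a long-form results table into a seed-averaged blocks-x-treatments matrix.

    Raises listing the missing (block, treatment) cells if incomplete.
    """
    needed = [*block_keys, treatment, metric]
    missing_cols = [c for c in needed if c not in results.columns]
    if missing_cols:
        raise InputError(f"results table missing column(s): {missing_cols}")
    pivot = results.pivot_table(
        index=list(block_keys), columns=treatment, values=metric, aggfunc="mean"
    )
    if pivot.isna().any().any():
        missing = [
            (idx, col)
            for col in pivot.columns
            for idx in pivot.index[pivot[col].isna()]
        ]
        raise InputError(f"incomplete score matrix; missing cells: {missing}")
    return pivot


def compare_methods(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    holm: bool = False,
) -> ComparisonResult:
    """Run the full Friedman -> Nemenyi -> pairwise Wilcoxon procedure.

    ``scores`` is a blocks-by-treatments matrix (see :func:`score_matrix`).
    The post hoc stages run only when the Friedman test is significant at
    ``alpha``.  Pairwise p-values are reported raw (as is conventional for
    this report layout); ``holm=True`` adds a Holm-adjusted column.
    """
    if scores.isna().any().any():
        missing = [
            (idx, col) for col in scores.columns for idx in scores.index[scores[col].isna()]
        ]
        raise InputError(f"incomplete score matrix; missing cells: {missing}")
    fr = friedman(scores)
    n, k = scores.shape
    ranks = scores.rank(axis=1)
    mean_ranks = ranks.mean(axis=0)

    rows = []
    cd: Optional[float] = None
    if fr.p_value < alpha:
        cd = nemenyi_cd(k, n, alpha)
        for a, b in combinations(scores.columns, 2):
            res = wilcoxon_signed_rank(
                scores[a].to_numpy(), scores[b].to_numpy(), alternative=alternative
            )
            rank_diff = abs(mean_ranks[a] - mean_ranks[b])
            rows.append(
                {
                    "comparison": f"{a} vs. {b}",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_effective": res.n_effective,
                    "exact": res.exact,
                    "verdict_0.05": res.p_value < 0.05,
                    "verdict_0.01": res.p_value < 0.01,
                    "nemenyi_rank_diff": rank_diff,
                    "nemenyi_significant": rank_diff >= cd,
                }
            )
    pairwise = pd.DataFrame(
        rows,
        columns=[
            "comparison",
            "statistic",
            "p_value",
            "n_effective",
            "exact",
            "verdict_0.05",
            "verdict_0.01",
            "nemenyi_rank_diff",
            "nemenyi_significant",
        ],
    )
    if holm and not pairwise.empty:
        order = np.argsort(pairwise["p_value"].to_numpy())
        m = len(pairwise)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * pairwise["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        pairwise["p_holm"] = adj
    return ComparisonResult(
        scores=scores,
        friedman=fr,
        mean_ranks=mean_ranks,
        nemenyi_critical_difference=cd,
        pairwise=pairwise,
        alpha=alpha,
    )
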