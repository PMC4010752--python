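"""Per-bin two-group nonparametric comparison (Mann-Whitney U).

Behavioral count and percentage data from small cohorts rarely meet
parametric assumptions, so groups are compared per time bin with the
Mann-Whitney U test. Small samples use an *exact* null distribution:
without ties, the classical count recurrence over all C(n_a+n_b, n_a)
label assignments; with ties, literal enumeration of label assignments
over midranks. Larger samples fall back to the tie-corrected normal
approximation with continuity correction.

Two-sided exact p is defined by the doubling convention,
``min(1, 2 * min-tail probability)`` — exact two-sided definitions vary,
so this choice is stated explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "MannWhitneyResult",
    "GroupComparison",
    "mann_whitney",
    "per_bin_comparison",
    "significance_stars",
    "holm_adjust",
]

EXACT_LIMIT = 16  # max pooled n for the exact small-sample mode


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class GroupComparison:
    """One per-bin group comparison with its significance stars."""

    bin_index: int
    metric_name: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str
    significance: str


@lru_cache(maxsize=None)
def _exact_u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of label assignments yielding each U in 0..n1*n2 (no ties).

    Classical count recurrence: the largest pooled observation belongs to
    group 1 (contributing n2 to U) or to group 2 (contributing 0), so
    f(n1, n2)[u] = f(n1-1, n2)[u-n2] + f(n1, n2-1)[u]. Equivalent to full
    enumeration of all C(n1+n2, n1) assignments without listing them.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    fa = _exact_u_counts(n1 - 1, n2)
    fb = _exact_u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(fa):
        out[u + n2] += c
    for u, c in enumerate(fb):
        out[u] += c
    return tuple(out)


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def _exact_p_no_ties(U: float, n1: int, n2: int) -> float:
    counts = np.array(_exact_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    u = int(round(U))
    lo = counts[: u + 1].sum() / total
    hi = counts[u:].sum() / total
    return min(1.0, 2.0 * min(lo, hi))


def _exact_p_ties(pooled: np.ndarray, n_a: int, U_obs: float) -> float:
    """Permutation enumeration of U over all label assignments (handles ties)."""
    n = len(pooled)
    ranks = rankdata(pooled)
    lo = hi = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = _u_from_ranks(ranks[list(idx)], n_a)
        total += 1
        if u <= U_obs + eps:
            lo += 1
        if u >= U_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def _normal_p(U: float, ranks: np.ndarray, n_a: int, n_b: int) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    # tie correction to the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(U - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * float(norm.sf(z)))


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for two independent groups.

    U is computed from rank sums with midranks for ties and reported for
    group ``a`` (``U_a + U_b = n_a * n_b``). ``method``:

    * ``"exact"`` — full-enumeration null distribution (count recurrence
      without ties; literal label-assignment enumeration with ties).
    * ``"normal"`` — tie-corrected normal approximation with continuity
      correction.
    * ``"auto"`` — exact when ``n_a + n_b <= 16``, else normal.

    Identical pooled values give p = 1. Empty groups raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney: both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("mann_whitney: values must be finite")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    U = _u_from_ranks(ranks[:n_a], n_a)

    if np.unique(pooled).size == 1:
        return MannWhitneyResult(U, 1.0, "exact")

    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if n_a + n_b <= EXACT_LIMIT else "normal"
    if method == "exact":
        if n_a + n_b > EXACT_LIMIT:
            raise ValueError(
                f"exact mode limited to pooled n <= {EXACT_LIMIT}, got {n_a + n_b}"
            )
        if has_ties:
            p = _exact_p_ties(pooled, n_a, U)
        else:
            p = _exact_p_no_ties(U, n_a, n_b)
        return MannWhitneyResult(U, p, "exact")
    if method == "normal":
        return MannWhitneyResult(U, _normal_p(U, ranks, n_a, n_b), "normal_approx")
    raise ValueError(f"unknown method {method!r}")


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default downstream)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def per_bin_comparison(
    table: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    method: str = "auto",
    holm: bool = False,
) -> list[GroupComparison]:
    """Compare two groups per bin on a long-format metric table.

    ``table`` is a metric table (``animal_id, bin_index, bin_start_s,
    ld_label, metric_name, value``). Missing values are dropped per bin;
    bins with fewer than two non-missing values in either group are
    skipped. Stars follow the 0.05 / 0.01 / 0.001 thresholds. No
    multiple-testing correction is applied across bins unless
    ``holm=True``.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    results: list[GroupComparison] = []
    for (metric, b), sub in table.groupby(["metric_name", "bin_index"], sort=True):
        sub = sub.dropna(subset=["value"])
        va = sub[sub["animal_id"].isin(group_a)]["value"].to_numpy()
        vb = sub[sub["animal_id"].isin(group_b)]["value"].to_numpy()
        if va.size < 2 or vb.size < 2:
            continue
        r = mann_whitney(va, vb, method=method)
        results.append(
            GroupComparison(
                bin_index=int(b),
                metric_name=str(metric),
                n_a=int(va.size),
                n_b=int(vb.size),
                U=r.U,
                p_two_sided=r.p_two_sided,
                method=r.method,
                significance=significance_stars(r.p_two_sided),
            )
        )
    if holm and results:
        adj = holm_adjust([c.p_two_sided for c in results])
        results = [
            GroupComparison(
                c.bin_index, c.metric_name, c.n_a, c.n_b, c.U, p, c.method,
                significance_stars(p),
            )
            for c, p in zip(results, adj)
        ]
    return results


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "metric": c.metric_name,
                "bin": c.bin_index,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "U": c.U,
                "p": c.p_two_sided,
                "method": c.method,
                "stars": c.significance,
            }
            for c in comparisons
        ]
    )
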