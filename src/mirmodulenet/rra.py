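"""Robust rank aggregation of per-iteration module rankings.

Each element's positions across the input lists are normalized by the
universe size; an element absent from a list gets the worst normalized rank
1.0.  For the sorted normalized ranks r(1) <= ... <= r(L) of one element,
the rho score is

    rho = min_k  P( at least k of L independent Uniform(0,1) <= r(k) )
        = min_k  sum_{j>=k} C(L,j) r(k)^j (1-r(k))^{L-j},

i.e. the best binomial order-statistic tail the element attains.  The
reported p-value is Bonferroni-corrected over the universe of elements:
corrected_p = min(1, rho * |universe|).  (The correction in the original R
implementation of this score multiplies by the number of lists instead;
correcting by the universe is the more conservative choice at typical
sizes and accounts for every element tested.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass
class AggregatedRanking:
    element_id: str
    rho_score: float
    corrected_p: float
    appearance_count: int
    final_rank: int = 0


def normalized_rank_matrix(
    ranked_lists: Sequence[Sequence[str]], universe: Iterable[str]
) -> "np.ndarray":
    """Matrix (element x list) of normalized ranks in (0, 1].

    Entry = (1-based position)/|universe| where the element is listed, 1.0
    where it is absent.  Row order follows sorted(universe).
    """
    uni = sorted(set(universe))
    n = len(uni)
    if n == 0:
        raise ValueError("empty universe")
    index = {e: i for i, e in enumerate(uni)}
    out = np.ones((n, len(ranked_lists)))
    for j, lst in enumerate(ranked_lists):
        if len(set(lst)) != len(lst):
            raise ValueError(f"list {j} contains duplicates")
        for pos, e in enumerate(lst, start=1):
            if e not in index:
                raise ValueError(f"element {e!r} not in universe")
            out[index[e], j] = pos / n
    return out


def rho_score(normalized_ranks: np.ndarray) -> float:
    """Minimum binomial order-statistic tail over all k (see module docs).

    Evaluated via the regularized incomplete beta function
    (P(Bin(L,r) >= k) = I_r(k, L-k+1)), numerically stable for L up to 1e4.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    if r.size == 0:
        raise ValueError("empty rank vector")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    L = r.size
    k = np.arange(1, L + 1)
    tails = stats.binom.sf(k - 1, L, r)
    return float(min(tails.min(), 1.0))


def aggregate(
    ranked_lists: Sequence[Sequence[str]], universe: Iterable[str]
) -> list[AggregatedRanking]:
    """Aggregate the lists into one prioritized ranking with p-values.

    Output sorted by corrected p ascending, ties by rho then element ID;
    final_rank assigned 1..|universe|.
    """
    if not ranked_lists:
        raise ValueError("need at least one ranked list")
    uni = sorted(set(universe))
    matrix = normalized_rank_matrix(ranked_lists, uni)
    appearances = {e: 0 for e in uni}
    for lst in ranked_lists:
        for e in lst:
            appearances[e] += 1
    out = []
    for i, e in enumerate(uni):
        rho = rho_score(matrix[i])
        out.append(
            AggregatedRanking(
                element_id=e,
                rho_score=rho,
                corrected_p=min(1.0, rho * len(uni)),
                appearance_count=appearances[e],
            )
        )
    out.sort(key=lambda a: (a.corrected_p, a.rho_score, a.element_id))
    for rank, a in enumerate(out, start=1):
        a.final_rank = rank
    return out


def mean_rank_baseline(
    ranked_lists: Sequence[Sequence[str]], universe: Iterable[str]
) -> list[str]:
    """Trivial aggregator (mean normalized rank); used only as a test baseline."""
    uni = sorted(set(universe))
    matrix = normalized_rank_matrix(ranked_lists, uni)
    means = matrix.mean(axis=1)
    return [e for _, e in sorted(zip(means, uni))]
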