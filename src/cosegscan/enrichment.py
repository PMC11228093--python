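"""Over-representation analysis: hypergeometric test with BH adjustment.

Given a candidate gene list, a background universe and flat term -> gene
sets, each term is scored by the upper-tail hypergeometric probability of
observing at least the attained overlap, and p-values are adjusted across
terms with the Benjamini-Hochberg step-up procedure. Both primitives are
implemented here (the tail in log space via log-gamma, for stability at
extreme counts) rather than delegated, so they can be cross-checked
against enumeration oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int        # candidate genes in term
    K: int        # universe genes in term
    n: int        # candidate genes total
    N: int        # universe size
    p_raw: float
    p_adj: float
    genes_hit: tuple[str, ...]


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    X counts marked items in a size-``n`` draw without replacement from a
    population of ``N`` items of which ``K`` are marked.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
        if n - i <= N - K
    ]
    if not log_terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enumerate_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Oracle: exact tail by counting draws with itertools-free combinatorics,
    P(X >= k) = sum_i C(K,i) C(N-K,n-i) / C(N,n). Integer-exact; test use."""
    denom = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / denom


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, aligned to input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def enrich(
    candidates: set[str],
    term_sets: dict[str, frozenset[str]],
    universe: set[str],
    min_size: int = 2,
    max_size: int = 500,
) -> pd.DataFrame:
    """Test each term's overlap with the candidate list.

    Candidates outside the universe are dropped with a warning; term gene
    sets are intersected with the universe and size-filtered before
    testing. One row per term with overlap >= 1, BH-adjusted across all
    tested terms, sorted by ascending p_raw with ties broken by term ID.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe = {g.upper() for g in universe}
    cand = {g.upper() for g in candidates}
    outside = cand - universe
    if outside:
        log.warning("dropping %d candidate gene(s) outside universe: %s",
                    len(outside), sorted(outside))
        cand &= universe

    N, n = len(universe), len(cand)
    rows = []
    n_size_filtered = 0
    for term in sorted(term_sets):
        genes = term_sets[term] & universe
        if not (min_size <= len(genes) <= max_size):
            n_size_filtered += 1
            continue
        hit = cand & genes
        if not hit:
            continue
        k, K = len(hit), len(genes)
        rows.append(
            {
                "term": term, "k": k, "K": K, "n": n, "N": N,
                "p_raw": hypergeom_upper_tail(k, K, n, N),
                "genes_hit": ",".join(sorted(hit)),
            }
        )
    if n_size_filtered:
        log.info("%d term(s) outside size bounds [%d, %d]",
                 n_size_filtered, min_size, max_size)
    df = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "p_raw", "genes_hit"]
    )
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df = df.sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df[["term", "k", "K", "n", "N", "p_raw", "p_adj", "genes_hit"]]
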