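"""Hypergeometric enrichment with fold change and Benjamini–Hochberg FDR.

Shared by the pathway (gene-set) report and de novo motif discovery.  The
urn follows the ZOOPS enrichment convention: the population is
target ∪ background, the sample is the target list, and the upper-tail
probability P[X >= k] scores over-representation of hits in the targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .tables_io import GeneSet

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "fold_enrichment",
    "benjamini_hochberg",
    "gene_set_enrichment",
    "enrichment_to_frame",
]


@dataclass
class EnrichmentResult:
    """Counts, fold enrichment and (adjusted) p-value for one item.

    ``fold_flag`` is "ok" normally, "infinite" when the background has no
    hits but the target does, and "degenerate" when neither side has hits.
    """

    item_id: str
    k_target: int
    n_target: int
    k_background: int
    n_background: int
    fold: float
    p_value: float
    bh_q: float = float("nan")
    fold_flag: str = "ok"

    @property
    def percent_target(self) -> float:
        return 100.0 * self.k_target / self.n_target if self.n_target else float("nan")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), summed in log space.

    k: hits in the sample (target), n: sample size, K: hits in the
    population, N: population size.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    hi = min(n, K)
    j = np.arange(k, hi + 1)
    logp = hypergeom.logpmf(j, N, K, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


def fold_enrichment(k_t: int, n_t: int, k_b: int, n_b: int) -> tuple[float, str]:
    """(k_t/n_t)/(k_b/n_b) with sentinels for empty-background cases."""
    if n_t <= 0 or n_b <= 0:
        raise ValueError("totals must be positive")
    if k_b == 0:
        if k_t == 0:
            return 1.0, "degenerate"
        return math.inf, "infinite"
    return (k_t / n_t) / (k_b / n_b), "ok"


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjusted values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def gene_set_enrichment(
    target: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
    method: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """Score each gene set for over-representation in the target list.

    ``background`` is the list of genes showing no regulation (disjoint from
    the target by contract).  ``method`` is "hypergeometric" (default) or
    "binomial" (background hit-rate as the success probability).  Results
    are sorted by p-value and carry BH-adjusted values.
    """
    tset, bset = set(target), set(background)
    if tset & bset:
        raise ValueError(f"target and background overlap: {sorted(tset & bset)[:5]} ...")
    if method not in ("hypergeometric", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    n_t, n_b = len(tset), len(bset)
    N = n_t + n_b

    results: list[EnrichmentResult] = []
    for gs in sets:
        k_t = len(tset & gs.members)
        k_b = len(bset & gs.members)
        if method == "hypergeometric":
            p = hypergeom_upper_tail(k_t, n_t, k_t + k_b, N)
        else:
            rate = k_b / n_b if n_b else 0.0
            p = float(binom.sf(k_t - 1, n_t, rate)) if rate > 0 else (1.0 if k_t == 0 else 0.0)
        fold, flag = fold_enrichment(k_t, n_t, k_b, n_b)
        results.append(
            EnrichmentResult(gs.set_id, k_t, n_t, k_b, n_b, fold, p, fold_flag=flag)
        )

    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.bh_q = q
    results.sort(key=lambda r: (r.p_value, r.item_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult], sets: Sequence[GeneSet] | None = None):
    """Pathway-report DataFrame: count, percent of target, percent of set,
    fold, p-value and Benjamini columns.

    Both percentage denominators are emitted because report conventions
    differ on whether "percent" is of the regulated list or of the pathway.
    """
    import pandas as pd

    set_sizes = {gs.set_id: len(gs.members) for gs in sets} if sets else {}
    rows = []
    for r in results:
        size = set_sizes.get(r.item_id)
        rows.append(
            {
                "item_id": r.item_id,
                "n_genes": r.k_target,
                "percent_of_target": r.percent_target,
                "percent_of_set": (100.0 * r.k_target / size) if size else float("nan"),
                "fold_enrichment": r.fold,
                "p_value": r.p_value,
                "benjamini": r.bh_q,
            }
        )
    return pd.DataFrame(rows)
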