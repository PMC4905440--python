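"""Set-overlap statistics: upper-tail hypergeometric enrichment with BH FDR.

The engine behind both the functional (GO/KEGG-style) term analysis and the
transcription-factor target association. The upper-tail hypergeometric
p-value equals a one-sided Fisher's exact test on the 2x2 overlap table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneSetCollection, ValidationError

ENRICHMENT_COLUMNS = ["term_id", "description", "k", "n", "K", "M", "p_value", "fdr"]


def hypergeom_upper(k: int, n: int, K: int, M: int) -> float:
    """P(overlap >= k) drawing n items from M of which K are marked.

    p = sum_{i=k}^{min(n,K)} C(K,i) C(M-K,n-i) / C(M,n).
    """
    if not (0 <= k <= min(n, K) and n <= M and K <= M):
        raise ValidationError(f"impossible hypergeometric counts k={k} n={n} K={K} M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_genes,
    collection: GeneSetCollection,
    universe: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set against a collection.

    The universe defaults to all genes annotated in the collection; a custom
    universe (e.g. the array's measured genes) may be supplied. For each term:
    k = |query ∩ term|, n = |query ∩ universe|, K = |term ∩ universe|,
    M = |universe|. BH FDR is applied across all terms of the collection.
    Results are sorted by ascending p, ties by term id.
    """
    query = set(query_genes)
    uni = frozenset(universe) if universe is not None else collection.universe
    effective = query & uni
    if not effective:
        raise ValidationError("query does not intersect the universe; nothing to test")
    n, M = len(effective), len(uni)
    rows = []
    for term, (desc, members) in collection.sets.items():
        term_in_uni = members & uni
        K = len(term_in_uni)
        k = len(effective & term_in_uni)
        p = hypergeom_upper(k, n, K, M) if K else 1.0
        rows.append((term, desc, k, n, K, M, p))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:7])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
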