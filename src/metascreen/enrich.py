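"""Hypergeometric over-representation analysis with BH adjustment.

One-sided enrichment of a query gene set against a GMT collection: for each
set, p = P(X >= k) with X ~ Hypergeometric(N, K, n) where N is the universe
size, K the (universe-restricted) set size, n the query size and k the
overlap; adjusted across sets by Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_ora(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Over-representation rows for every set in the collection, sorted by
    adjusted then raw p (set name breaks remaining ties).

    The query must be contained in the universe; each annotation set is
    intersected with the universe before testing.
    """
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        members_u = set(m.upper() for m in members) & universe
        K = len(members_u)
        overlap = sorted(query & members_u)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "query_size_n": n,
                "universe_N": N,
                "p": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p_adj", "p", "set_name"], kind="stable").reset_index(drop=True)
    return df[
        ["set_name", "overlap_k", "set_size_K", "query_size_n", "universe_N",
         "p", "p_adj", "overlap_genes"]
    ]
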