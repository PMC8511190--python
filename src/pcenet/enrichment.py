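"""Over-representation analysis of protein sets against annotation terms.

One-sided hypergeometric tests with Benjamini-Hochberg control across all
terms in a collection, plus the Strength effect size
log10(observed / expected), where expected = |term| * |query| / |background|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import AnnotationCollection
from .wgcna import bh_adjust

__all__ = ["enrich"]


def enrich(
    query: set[str], annotations: AnnotationCollection, p_max: float = 0.05
) -> pd.DataFrame:
    """Term over-representation in a query protein set.

    Per term: observed = |query & term|; expected under random draws from
    the background; p = P(X >= observed) from the hypergeometric tail with
    population |background|, successes |term| and draws |query|. BH q is
    computed across every term in the collection; rows with observed = 0
    (Strength undefined) are then omitted and the rest filtered at
    p < p_max and sorted by ascending q.
    """
    query = set(query)
    stray = query - annotations.background
    if stray:
        raise ValueError(f"query proteins outside the background: {sorted(stray)[:10]}")
    N = len(annotations.background)
    n_draw = len(query)
    rows = []
    for term, members in annotations.terms.items():
        K = len(members)
        obs = len(query & members)
        expected = K * n_draw / N
        p = float(hypergeom.sf(obs - 1, N, K, n_draw))
        rows.append(
            {
                "term": term,
                "observed": obs,
                "expected": expected,
                "strength": np.log10(obs / expected) if obs > 0 else np.nan,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["term", "observed", "expected", "strength", "p"]
    )
    if table.empty:
        table["q"] = []
        return table
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[(table["observed"] > 0) & (table["p"] < p_max)]
    return table.sort_values(["q", "p", "term"]).reset_index(drop=True)
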