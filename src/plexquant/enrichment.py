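"""GO-term over-representation with the quantified-proteome background.

The statistic is the hypergeometric upper tail of the query/term overlap,
with the set of all proteins quantified in the plex as the background
universe.  p-values are Benjamini-Hochberg adjusted within each GO
namespace (BP/MF/CC); up- and down-regulated query sets are analyzed
separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_TERM_SIZE = 5
DEFAULT_MAX_TERM_SIZE = 500


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if k < 0 or K < 0 or n < 0 or K > N or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    # sf is the stable (log-space capable) survival function; sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def go_ora(
    query: set,
    background: set,
    annotations: pd.DataFrame,
    direction: str = "up",
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    max_term_size: int = DEFAULT_MAX_TERM_SIZE,
    adjust_within_namespace: bool = True,
) -> pd.DataFrame:
    """Over-representation of annotation terms in ``query`` vs ``background``.

    ``annotations`` has columns protein_id/term_id/term_name/namespace.
    Term membership is intersected with the background before the size
    filter (5 <= K <= 500 by default).  Returns one row per surviving term
    with hypergeometric p and BH-adjusted p, sorted by adjusted p.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    cols = ["term_id", "term_name", "namespace", "k", "K", "n", "N", "p_value", "adj_p", "direction"]
    if not len(query):
        warnings.warn("empty query set; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=cols)
    if annotations.empty:
        return pd.DataFrame(columns=cols)
    ann = annotations[annotations["protein_id"].isin(background)]
    N, n = len(background), len(query)
    rows = []
    for (tid, tname, ns), sub in ann.groupby(["term_id", "term_name", "namespace"]):
        members = set(sub["protein_id"])
        K = len(members)
        if not min_term_size <= K <= max_term_size:
            continue
        k = len(members & query)
        rows.append((tid, tname, ns, k, K, n, N, hypergeom_upper_tail(k, K, n, N), np.nan, direction))
    out = pd.DataFrame(rows, columns=cols)
    if out.empty:
        return out
    if adjust_within_namespace:
        for ns, idx in out.groupby("namespace").groups.items():
            out.loc[idx, "adj_p"] = bh_adjust(out.loc[idx, "p_value"])
    else:
        out["adj_p"] = bh_adjust(out["p_value"])
    return out.sort_values(["adj_p", "p_value"]).reset_index(drop=True)
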