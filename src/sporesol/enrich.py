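"""Hypergeometric over-representation of annotation terms per cluster.

One-sided upper-tail test: for a cluster of size n drawn from a
background of N proteins of which K carry the term, the p-value is
P(X >= k) with X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg
q-values are computed per cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

__all__ = ["hypergeometric_pvalue", "benjamini_hochberg", "enrich_clusters"]

logger = logging.getLogger(__name__)


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``k`` successes in a sample of ``n`` drawn without replacement from
    ``N`` objects of which ``K`` are successes.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ParameterError(f"invalid configuration k={k}, n={n}, K={K}, N={N}")
    if k > K or n - k > N - K:
        raise ParameterError(
            f"impossible configuration: k={k} successes with K={K}, "
            f"{n - k} failures with {N - K}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in the p ordering)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def enrich_clusters(
    assignments: pd.DataFrame,
    annotations: dict[str, dict],
    background: set[str],
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Test every (term, cluster) combination against the background.

    Parameters
    ----------
    assignments
        DataFrame with ``protein_id`` and a grouping column
        (``class_label`` if present, else ``cluster_id``).
    annotations
        term_id -> {"term_name", "members"} as read by
        :func:`sporesol.quantio.read_annotation_map`.
    background
        Reference protein set; must contain every clustered protein.
        Term membership is restricted to it before counting.
    min_term_size
        Terms with fewer background members are skipped.

    Returns
    -------
    pandas.DataFrame sorted by p-value, with BH q-values per cluster.
    """
    group_col = "class_label" if "class_label" in assignments.columns else "cluster_id"
    clustered = set(assignments["protein_id"])
    stray = clustered - set(background)
    if stray:
        raise ValidationError(f"clustered protein(s) not in background: {sorted(stray)[:5]}")

    N = len(background)
    rows = []
    for term_id, entry in annotations.items():
        members = set(entry["members"]) & set(background)
        K = len(members)
        if K < min_term_size:
            logger.info("term %s skipped: %d background member(s)", term_id, K)
            continue
        for cluster, sub in assignments.groupby(group_col, sort=False, observed=True):
            cluster_proteins = set(sub["protein_id"])
            n = len(cluster_proteins)
            k = len(cluster_proteins & members)
            rows.append(
                {
                    "term_id": term_id,
                    "term_name": entry["term_name"],
                    "cluster": cluster,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "fraction": k / n if n else np.nan,
                    "p_value": hypergeometric_pvalue(k, n, K, N),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "cluster", "k", "n", "K", "N", "fraction", "p_value"],
    )
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        return result
    result["q_value"] = np.nan
    for cluster, idx in result.groupby("cluster", observed=True).groups.items():
        result.loc[idx, "q_value"] = benjamini_hochberg(result.loc[idx, "p_value"].to_numpy())
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)
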