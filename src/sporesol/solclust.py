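"""Trajectory clustering, class labeling and downstream set analyses.

Mean solubility trajectories are clustered by complete-linkage
agglomerative clustering on Euclidean distance; the tree is cut at the
smallest distance threshold that yields the requested number of flat
clusters.  Cluster median profiles are then mapped onto five canonical
solubility classes by shape rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import ParameterError, ValidationError

__all__ = [
    "CLASS_LABELS",
    "ClusterProfile",
    "LabelRules",
    "cluster_trajectories",
    "assign_class_labels",
    "extract_changing_set",
    "pca_protein_properties",
    "interaction_pairs",
]

LABEL_MOSTLY_PELLET = "mostly_pellet"
LABEL_MOSTLY_SUPERNATANT = "mostly_supernatant"
LABEL_TRANSIENT = "transient_solubilization"
LABEL_GRADUAL_DESOL = "gradual_desolubilization"
LABEL_GRADUAL_SOL = "gradual_solubilization"

CLASS_LABELS = (
    LABEL_MOSTLY_PELLET,
    LABEL_MOSTLY_SUPERNATANT,
    LABEL_TRANSIENT,
    LABEL_GRADUAL_DESOL,
    LABEL_GRADUAL_SOL,
)

#: classes whose trajectories change during the time course
CHANGING_LABELS = (LABEL_TRANSIENT, LABEL_GRADUAL_DESOL, LABEL_GRADUAL_SOL)


@dataclass
class ClusterProfile:
    cluster_id: int
    median: np.ndarray
    size: int


@dataclass
class LabelRules:
    """Thresholds for the shape-based class rules.

    static_range
        A profile whose total range (max - min) is below this is static.
    dip_margin
        For the transient class both endpoints must exceed the interior
        minimum by this margin.
    trend_margin
        Minimal end-to-start difference for a monotone-trend class.
    """

    static_range: float = 0.25
    dip_margin: float = 0.20
    trend_margin: float = 0.15


def cluster_trajectories(
    matrix: pd.DataFrame,
    n_clusters: int = 5,
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> tuple[pd.DataFrame, list[ClusterProfile], dict]:
    """Cluster trajectories and cut the tree into ``n_clusters`` groups.

    Parameters
    ----------
    matrix
        proteins x time points, complete (no missing cells).
    n_clusters
        Number of flat clusters to produce by cutting the dendrogram at
        the smallest distance threshold that yields exactly this many.

    Returns
    -------
    assignments
        DataFrame (protein_id, cluster_id) in input row order; cluster
        ids are 1..n_clusters ordered by first appearance.
    profiles
        Per-cluster median trajectory and size.
    dendrogram
        Nested-dict serialization of the merge tree (JSON friendly).
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if np.isnan(values).any():
        raise ValidationError("trajectory matrix contains missing cells")
    if n_clusters > n:
        raise ParameterError(f"n_clusters={n_clusters} exceeds {n} trajectories")

    link = hierarchy.linkage(values, method=linkage_method, metric=metric)
    heights = link[:, 2]

    if n_clusters == n:
        flat = np.arange(1, n + 1)
    else:
        # cutting just above the (n - k)-th merge height gives k clusters
        # when heights are distinct; ties can make exactly-k unattainable
        h_low = heights[n - n_clusters - 1] if n_clusters < n else 0.0
        h_high = heights[n - n_clusters] if n_clusters >= 1 else np.inf
        if h_high <= h_low or np.isclose(h_high, h_low):
            raise ParameterError(
                f"cannot cut tree into exactly {n_clusters} clusters: "
                f"tied merge heights at {h_low:.6g}"
            )
        threshold = 0.5 * (h_low + h_high)
        flat = hierarchy.fcluster(link, t=threshold, criterion="distance")
        if len(set(flat)) != n_clusters:  # pragma: no cover - defensive
            raise ParameterError(
                f"distance cut produced {len(set(flat))} clusters instead of {n_clusters}"
            )

    # relabel cluster ids by first appearance for order invariance of output
    relabel: dict[int, int] = {}
    cluster_ids = np.empty(n, dtype=int)
    for i, c in enumerate(flat):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        cluster_ids[i] = relabel[c]

    assignments = pd.DataFrame({"protein_id": matrix.index, "cluster_id": cluster_ids})
    profiles = []
    for cid in range(1, len(relabel) + 1):
        members = values[cluster_ids == cid]
        profiles.append(
            ClusterProfile(cluster_id=cid, median=np.median(members, axis=0), size=len(members))
        )
    tree = _tree_to_dict(hierarchy.to_tree(link), list(matrix.index))
    return assignments, profiles, tree


def _tree_to_dict(node, labels) -> dict:
    if node.is_leaf():
        return {"leaf": str(labels[node.id])}
    return {
        "height": float(node.dist),
        "count": int(node.count),
        "children": [_tree_to_dict(node.left, labels), _tree_to_dict(node.right, labels)],
    }


def classify_profile(median: np.ndarray, rules: LabelRules | None = None) -> str:
    """Map a median trajectory onto one canonical solubility class."""
    rules = rules or LabelRules()
    m = np.asarray(median, dtype=float)
    if m.size < 4:
        raise ParameterError("profiles need at least 4 time points")
    r = m.max() - m.min()
    if r < rules.static_range:
        return LABEL_MOSTLY_PELLET if m.mean() >= 0.5 else LABEL_MOSTLY_SUPERNATANT
    imin = int(np.argmin(m))
    if 0 < imin < m.size - 1 and m[0] > m.min() + rules.dip_margin and m[-1] > m.min() + rules.dip_margin:
        return LABEL_TRANSIENT
    if m[-1] - m[0] >= rules.trend_margin:
        return LABEL_GRADUAL_DESOL
    if m[0] - m[-1] >= rules.trend_margin:
        return LABEL_GRADUAL_SOL
    raise ValidationError(f"profile {np.round(m, 3).tolist()} matches no class rule")


def assign_class_labels(
    profiles: list[ClusterProfile],
    rules: LabelRules | None = None,
) -> dict[int, str]:
    """Label each cluster profile; each canonical label used at most once."""
    labels: dict[int, str] = {}
    used: dict[str, int] = {}
    for prof in profiles:
        label = classify_profile(prof.median, rules)
        if label in used:
            other = next(p for p in profiles if p.cluster_id == used[label])
            raise ValidationError(
                f"clusters {used[label]} and {prof.cluster_id} both classify as {label}: "
                f"medians {np.round(other.median, 3).tolist()} and "
                f"{np.round(prof.median, 3).tolist()}"
            )
        used[label] = prof.cluster_id
        labels[prof.cluster_id] = label
    return labels


def extract_changing_set(assignments: pd.DataFrame) -> list[str]:
    """Proteins in the three dynamic classes, in input order.

    ``assignments`` must carry a ``class_label`` column.
    """
    if "class_label" not in assignments.columns:
        raise ValidationError("assignments lack a class_label column")
    mask = assignments["class_label"].isin(CHANGING_LABELS)
    return assignments.loc[mask, "protein_id"].tolist()


def pca_protein_properties(props: pd.DataFrame) -> dict:
    """PCA of standardized protein properties.

    Features are standardized to zero mean and unit (population)
    variance; zero-variance features are dropped with a warning.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive.

    Returns a dict with ``loadings`` (features x components),
    ``scores`` (proteins x components) and ``explained_variance_ratio``.
    """
    numeric = props.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ParameterError("need at least 2 numeric features")
    if numeric.shape[0] < 3:
        raise ParameterError("need at least 3 proteins")
    if numeric.isna().any().any():
        raise ValidationError("properties contain missing values")
    std = numeric.std(ddof=0)
    flat = std[std == 0].index.tolist()
    if flat:
        warnings.warn(f"dropping zero-variance feature(s): {flat}", stacklevel=2)
        numeric = numeric.drop(columns=flat)
        std = std.drop(flat)
    z = (numeric - numeric.mean()) / std
    x = z.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(vt.shape[0]):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s**2
    evr = var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return {
        "loadings": pd.DataFrame(vt.T, index=numeric.columns, columns=comps),
        "scores": pd.DataFrame(u * s, index=numeric.index, columns=comps),
        "explained_variance_ratio": pd.Series(evr, index=comps),
    }


def interaction_pairs(
    changing_set: list[str],
    edges: list[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Edges whose both endpoints lie in ``changing_set`` (each once)."""
    members = set(changing_set)
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for a, b in edges:
        if a == b:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in seen:
            continue
        if a in members and b in members:
            seen.add(pair)
            out.append(pair)
    return out
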