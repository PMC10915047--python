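"""Hierarchical clustering of standardized preference summaries.

Participants are grouped by agglomerative clustering with *centroid
linkage* (inter-cluster distance = Euclidean distance between cluster
centroids) on z-scored response columns.  The dendrogram is cut into
k = 2, 3 and 4 groups and the partition minimizing the Bayesian
Information Criterion of a multivariate-normal model is selected:

    BIC = -2 log L + m log n,
    log L = sum_k [ n_k log(n_k / n) + sum_{i in k} log N(x_i; mu_k, S_k) ]

(the classification log-likelihood of the hard partition, mixing
proportions at their ML values n_k/n).  The default covariance structure
is a *tied diagonal* matrix -- per-cluster means, one pooled within-cluster
variance per dimension, m = (k-1) + kd + d -- because it is the weakest
model under which splitting a genuinely homogeneous group cannot buy a
large likelihood gain; per-cluster ``diagonal`` (m = (k-1) + 2kd) and
``spherical`` (m = (k-1) + kd + k) structures are available as options.

Centroid linkage can produce height inversions (a merge lower than an
earlier one); cuts are therefore taken by merge order, not height, and
inversions are flagged.  BIC ties resolve toward the smaller k
(parsimony); k = 1 is never considered.

Criterion presets mirror the study's clustering variants: a single
(feature, instruction) response, all six responses, the dangerous or
harmless triplet, or all six plus the SPQ score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import FEATURES, INSTRUCTIONS

__all__ = ["ClusteringResult", "standardize", "centroid_linkage", "cut_tree",
           "bic_for_partition", "select_clusters", "criterion_columns",
           "CANDIDATE_K", "VARIANCE_FLOOR"]

CANDIDATE_K = (2, 3, 4)
VARIANCE_FLOOR = 1e-6


def standardize(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Z-score each column (sample SD, n-1 denominator).

    Raises on a zero-variance column, naming it.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        names = [str(j) for j in range(x.shape[1])]
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance column {names[dead[0]]!r} cannot be standardized")
    return (x - x.mean(axis=0)) / sd


def centroid_linkage(z: np.ndarray) -> np.ndarray:
    """Centroid-linkage merge history in SciPy linkage format.

    Rows are (idx_a, idx_b, centroid distance, cluster size).  Height
    inversions are legitimate for centroid linkage; a warning is issued
    when they occur.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if len(z) < 2:
        raise ValueError("need at least two rows to cluster")
    link = hierarchy.linkage(pdist(z), method="centroid")
    heights = link[:, 2]
    if np.any(np.diff(heights) < 0):
        warnings.warn("centroid linkage produced height inversions; "
                      "cuts are by merge order", stacklevel=2)
    return link


def cut_tree(link: np.ndarray, k: int) -> np.ndarray:
    """Labels from undoing the last k - 1 merges (cut by merge order).

    Centroid linkage can invert merge heights, and a height-based cut is
    then ill-defined (scipy's cut_tree mislabels such trees); replaying
    the first n - k merges is always well-defined.  Labels are numbered
    by each cluster's smallest row index.
    """
    n = link.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i in range(n - k):
        a, b = int(link[i, 0]), int(link[i, 1])
        members[n + i] = members.pop(a) + members.pop(b)
    labels = np.empty(n, dtype=int)
    for lab, rows in enumerate(sorted(members.values(), key=min)):
        labels[rows] = lab
    return labels


def bic_for_partition(z: np.ndarray, labels: np.ndarray,
                      covariance: str = "tied") -> float:
    """Gaussian BIC of a hard partition of the rows of ``z``.

    The log-likelihood is the classification likelihood of a Gaussian
    mixture at the partition's ML parameters: per-cluster means, mixing
    proportions n_k/n, and a diagonal covariance that is either pooled
    across clusters (``tied``, the default), per-cluster (``diagonal``)
    or per-cluster isotropic (``spherical``).  ML variances are floored
    at 1e-6 per dimension so singleton or degenerate clusters stay
    finite.  Parameter counts: tied (k-1) + kd + d, diagonal
    (k-1) + 2kd, spherical (k-1) + kd + k.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    labels = np.asarray(labels)
    n, d = z.shape
    if labels.shape != (n,):
        raise ValueError("labels must align with the rows of z")
    labs = np.unique(labels)
    k = len(labs)
    counts, means, ssq = [], [], []
    for lab in labs:
        pts = z[labels == lab]
        if pts.shape[0] == 0:
            raise ValueError(f"empty cluster {lab!r}")
        counts.append(len(pts))
        means.append(pts.mean(axis=0))
        ssq.append(((pts - means[-1]) ** 2).sum(axis=0))
    counts = np.asarray(counts)
    floored = False

    def floor(var: np.ndarray) -> np.ndarray:
        nonlocal floored
        if np.any(var < VARIANCE_FLOOR):
            floored = True
        return np.maximum(var, VARIANCE_FLOOR)

    loglik = float(np.sum(counts * np.log(counts / n)))
    if covariance == "tied":
        var = floor(np.sum(ssq, axis=0) / n)
        for nk, s in zip(counts, ssq):
            loglik += -0.5 * (nk * np.sum(np.log(2 * np.pi * var))
                              + np.sum(s / var))
        m = (k - 1) + k * d + d
    elif covariance == "diagonal":
        for nk, s in zip(counts, ssq):
            var = floor(s / nk)
            loglik += -0.5 * (nk * np.sum(np.log(2 * np.pi * var))
                              + np.sum(s / var))
        m = (k - 1) + 2 * k * d
    elif covariance == "spherical":
        for nk, s in zip(counts, ssq):
            var = floor(np.full(d, s.sum() / (nk * d)))
            loglik += -0.5 * (nk * np.sum(np.log(2 * np.pi * var))
                              + np.sum(s / var))
        m = (k - 1) + k * d + k
    else:
        raise ValueError(f"unknown covariance structure {covariance!r}")
    if floored:
        warnings.warn("variance floor applied to a (near-)degenerate cluster",
                      stacklevel=2)
    return float(-2.0 * loglik + m * np.log(n))


@dataclass
class ClusteringResult:
    """Linkage tree, per-k BIC, and the selected hard partition."""

    variables: list[str]
    linkage: np.ndarray
    bic: dict[int, float]
    selected_k: int
    labels: np.ndarray
    participant_ids: list[str] = field(default_factory=list)
    inversions: bool = False

    def labels_frame(self, criterion: str = "") -> pd.DataFrame:
        ids = self.participant_ids or [str(j) for j in range(len(self.labels))]
        return pd.DataFrame({"participant_id": ids, "criterion": criterion,
                             "selected_k": self.selected_k, "label": self.labels})


def select_clusters(matrix: pd.DataFrame | np.ndarray,
                    candidate_k: tuple[int, ...] = CANDIDATE_K,
                    covariance: str = "tied") -> ClusteringResult:
    """Standardize, cluster, and pick the partition with minimal BIC.

    ``matrix`` is participants x chosen response variables (>= 8 rows).
    Ties in BIC resolve toward the smaller k.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        names = list(matrix.columns)
    else:
        m = np.atleast_2d(np.asarray(matrix, dtype=float))
        ids = [str(j) for j in range(m.shape[0])]
        names = [str(j) for j in range(m.shape[1])]
    z = standardize(matrix if isinstance(matrix, pd.DataFrame)
                    else np.asarray(matrix, dtype=float).reshape(len(ids), -1))
    if z.shape[0] < 8:
        raise ValueError(f"need >= 8 participants to cluster, got {z.shape[0]}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        link = centroid_linkage(z)
    inversions = any("inversion" in str(w.message) for w in caught)

    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in candidate_k:
        labels = cut_tree(link, k)
        labels_by_k[k] = labels
        bic[k] = bic_for_partition(z, labels, covariance=covariance)
    selected_k = min(sorted(bic), key=lambda k: (bic[k], k))
    return ClusteringResult(variables=names, linkage=link, bic=bic,
                            selected_k=selected_k, labels=labels_by_k[selected_k],
                            participant_ids=ids, inversions=inversions)


def criterion_columns(criterion: str) -> list[str]:
    """Resolve a clustering-criterion preset to summary-matrix columns.

    Presets: ``single:<feature>:<instruction>`` (one response, as in the
    per-panel clusterings), ``all-features``, ``dangerous``, ``harmless``
    and ``all-plus-spq``.
    """
    all_features = [f"{f}_{i}" for f in FEATURES for i in INSTRUCTIONS]
    if criterion.startswith("single:"):
        try:
            _, feature, instruction = criterion.split(":")
        except ValueError:
            raise ValueError(f"malformed criterion {criterion!r}; expected "
                             "single:<feature>:<instruction>") from None
        col = f"{feature}_{instruction}"
        if col not in all_features:
            raise ValueError(f"unknown response {col!r}")
        return [col]
    presets = {
        "all-features": all_features,
        "dangerous": [f"{f}_dangerous" for f in FEATURES],
        "harmless": [f"{f}_harmless" for f in FEATURES],
        "all-plus-spq": ["spq", *all_features],
    }
    if criterion not in presets:
        raise ValueError(f"unknown clustering criterion {criterion!r}")
    return presets[criterion]
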