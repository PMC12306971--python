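"""Data-driven discovery of response archetypes.

Trials are represented by their normalized post-stimulus speed (1 s, 100
bins, baseline-subtracted).  PCA reduces them to the first three principal
components and agglomerative hierarchical clustering (Ward linkage,
Euclidean distance) in that space separates stereotyped response types.
This exploratory view cross-checks the threshold classifier: on synthetic
data with well-separated motifs the two labelings agree strongly, while on
heterogeneous cohorts cluster boundaries drift with group composition —
which is exactly why group comparisons use the threshold definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .errors import DataError, ParameterError
from .kinematics import N_PRE, TrialTrace

N_COMPONENTS = 3
DEFAULT_K = 4


@dataclass
class ResponseEmbedding:
    """PC scores of trials plus the fitted basis and cluster labels."""

    scores: np.ndarray  # (n_trials, 3)
    components: np.ndarray  # (3, 100)
    mean: np.ndarray  # (100,)
    explained_variance_ratio: np.ndarray  # (3,), non-increasing
    clusters: np.ndarray | None = None
    trial_ids: list = field(default_factory=list)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix) - self.mean) @ self.components.T


def trials_matrix(traces: list[TrialTrace]) -> np.ndarray:
    """Stack valid trials' normalized post-stimulus speed into (n, 100)."""
    rows = [t.normalized_speed[N_PRE:] for t in traces if t.valid]
    if not rows:
        raise DataError("no valid trials")
    return np.vstack(rows)


def fit_response_pca(matrix: np.ndarray,
                     n_components: int = N_COMPONENTS) -> ResponseEmbedding:
    """Mean-centered PCA of normalized post-stimulus speed traces.

    ``matrix`` is (n_trials, n_bins); requires at least ``n_components + 1``
    trials.  Zero-variance input yields all-zero scores.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ParameterError("expected a 2-d trials x bins matrix")
    n = matrix.shape[0]
    if n <= n_components:
        raise ParameterError(
            f"need more than {n_components} trials, got {n}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    evr = pca.explained_variance_ratio_
    if not np.isfinite(evr).all():  # degenerate zero-variance input
        evr = np.zeros(n_components)
        scores = np.zeros_like(scores)
    return ResponseEmbedding(
        scores=scores,
        components=pca.components_,
        mean=pca.mean_,
        explained_variance_ratio=evr,
    )


def cluster_trials(embedding: ResponseEmbedding, k: int = DEFAULT_K) -> np.ndarray:
    """Ward-linkage agglomerative clustering of the PC scores, cut at k."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    n = embedding.scores.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds the {n} available trials")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(embedding.scores)
    embedding.clusters = labels
    return labels


def compare_labelings(
    cluster_labels: np.ndarray, threshold_labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand agreement between the data-driven
    clusters and the threshold classifier's labels (same trial order)."""
    cluster_labels = np.asarray(cluster_labels)
    threshold_labels = np.asarray(threshold_labels)
    if len(cluster_labels) != len(threshold_labels):
        raise DataError("labelings cover different trial sets")
    table = pd.crosstab(
        pd.Series(threshold_labels, name="threshold"),
        pd.Series(cluster_labels, name="cluster"),
    )
    ari = float(adjusted_rand_score(threshold_labels, cluster_labels))
    return table, ari


def dendrogram_newick(embedding: ResponseEmbedding) -> str:
    """Ward dendrogram of the PC scores as a Newick-style nested string."""
    z = linkage(embedding.scores, method="ward")
    root = to_tree(z)

    def fmt(node) -> str:
        if node.is_leaf():
            return f"t{node.id}"
        return f"({fmt(node.left)},{fmt(node.right)}):{node.dist:.4f}"

    return fmt(root) + ";"
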