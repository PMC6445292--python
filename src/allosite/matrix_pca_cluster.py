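"""PCA of per-condition interaction-strength matrices and single-linkage clustering.

Each condition's average interaction matrix is flattened to its upper
triangle (the matrices are symmetric with zero diagonal, so this loses
nothing), the flattened vectors are mean-centred across conditions and
decomposed by SVD.  All principal components are retained by default, so
Euclidean distances between condition scores equal the distances between the
raw flattened matrices; a 2-component mode exists for plotting.  Conditions
are then grouped by agglomerative single linkage on those distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .psn import InteractionMatrix

__all__ = ["ConditionEmbedding", "matrix_pca", "single_linkage"]


@dataclass
class ConditionEmbedding:
    condition_labels: list[str]
    scores: np.ndarray  # (n_conditions, n_components)
    eigenvalues: np.ndarray  # descending

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.condition_labels, columns=cols)


def matrix_pca(
    matrices: list[InteractionMatrix],
    n_components: int | None = None,
) -> ConditionEmbedding:
    """Embed interaction matrices in a shared principal-component space."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    labels0 = matrices[0].residue_labels
    for m in matrices[1:]:
        if m.residue_labels != labels0:
            raise ValueError("residue sets of the matrices do not match")
    n = len(labels0)
    iu, ju = np.triu_indices(n, k=1)
    x = np.stack([m.values[iu, ju] for m in matrices])  # (n_cond, n_pairs)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s  # preserves pairwise Euclidean distances of centred rows
    eigenvalues = s ** 2 / max(len(matrices) - 1, 1)
    if n_components is not None:
        scores = scores[:, :n_components]
        eigenvalues = eigenvalues[:n_components]
    return ConditionEmbedding([m.condition_label for m in matrices], scores, eigenvalues)


def single_linkage(
    embedding: ConditionEmbedding,
    n_clusters: int | None = None,
    height: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-linkage clustering of condition scores (Euclidean distances).

    Returns ``(labels, linkage_matrix)``; cluster labels are 1-based and
    deterministic.  Exactly one of ``n_clusters``/``height`` must be given.
    """
    scores = embedding.scores
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 points")
    tree = linkage(scores, method="single", metric="euclidean")
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    if n_clusters is not None:
        if n_clusters > scores.shape[0]:
            raise ValueError("more clusters requested than points")
        labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(tree, t=height, criterion="distance")
    return labels, tree
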