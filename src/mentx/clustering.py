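"""Unsupervised sample structure: PCA and signature-gene hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import LOG2, ExpressionMatrix, SampleAnnotation, ValidationError


@dataclass
class PcaResult:
    scores: pd.DataFrame            # samples x components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_samples(m: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples in gene space (genes centered, SVD-based).

    Components are ordered by decreasing explained variance; scores carry a
    deterministic sign convention (largest-magnitude loading positive).
    """
    if m.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    X = m.values.to_numpy(float).T            # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        raise ValidationError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: per component, the gene loading of largest magnitude is positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / (X.shape[0] - 1)
    ratio = var / var.sum()
    k = n_components or len(s)
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=m.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(scores, ratio[:k])


@dataclass
class ClusterAssignment:
    """Flat cut of an agglomerative dendrogram into k clusters."""

    labels: pd.Series                 # sample_id -> cluster label (1..k)
    linkage_matrix: np.ndarray
    distance: str
    linkage_method: str

    @property
    def k(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between columns (samples)."""
    C = np.corrcoef(X.T)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def hierarchical_cluster(
    m: ExpressionMatrix,
    k: int = 3,
    genes: Sequence[str] | None = None,
    distance: str = "correlation",
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of samples, cut at ``k`` clusters.

    Default distance is 1 − Pearson correlation across the supplied genes
    (the expression-heatmap convention) with average linkage. The distance
    matrix is computed explicitly, so ties are broken by scipy's
    deterministic lowest-index rule and runs are reproducible.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > m.n_samples:
        raise ValidationError(f"k={k} exceeds sample count {m.n_samples}")
    vals = m.values
    if genes is not None:
        missing = [g for g in genes if g not in vals.index]
        if missing:
            raise ValidationError(f"signature genes missing from matrix: {missing[:5]}")
        vals = vals.loc[list(genes)]
    X = vals.to_numpy(float)
    if distance == "correlation":
        D = _correlation_distance(X)
        Z = linkage(squareform(D, checks=False), method=linkage_method)
    elif distance == "euclidean":
        Z = linkage(X.T, method=linkage_method, metric="euclidean")
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    flat = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=vals.columns, name="cluster")
    return ClusterAssignment(labels, Z, distance, linkage_method)


def cluster_composition(
    assignment: ClusterAssignment, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Counts of each WHO x subgroup category per cluster.

    Samples without an annotation record are tallied under 'unknown'.
    Row marginals equal cluster sizes; column marginals equal annotation
    totals for clustered samples.
    """
    cat = {a.sample_id: a.category for a in annotations}
    rows = []
    for s, c in assignment.labels.items():
        rows.append({"cluster": int(c), "category": cat.get(str(s), "unknown")})
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="cluster", columns="category", aggfunc=len, fill_value=0
    )
    table.columns = [c[-1] if isinstance(c, tuple) else c for c in table.columns]
    return table
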