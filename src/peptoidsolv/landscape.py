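"""Conformational landscape: UMAP embedding, HDBSCAN clustering, summaries.

The pipeline mirrors common practice for enhanced-sampling conformational
ensembles: featurize each backbone as its internal distance matrix, embed
the flattened features in 2-D with UMAP (15 neighbours, min_dist 0.0),
cluster the embedding with HDBSCAN (minimum cluster size 10, 3 core-point
neighbours, 0.2 merge distance), and summarise each cluster by its
population fraction and the conformation reconstructed from the cluster-mean
feature, reporting its end-to-end distance.

The model/results split follows the statsmodels convention:
``ConformationalLandscape(confs).fit(seed=42)`` returns a
:class:`LandscapeResult` carrying the embedding, labels and summaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .conformation import Conformation, end_to_end, featurize, reconstruct

__all__ = [
    "embed",
    "cluster",
    "summarize_clusters",
    "ClusterSummary",
    "ConformationalLandscape",
    "LandscapeResult",
]


def embed(
    features: Sequence[np.ndarray],
    n_neighbors: int = 15,
    min_dist: float = 0.0,
    seed: int = 42,
) -> np.ndarray:
    """2-D UMAP embedding of flattened internal-distance features.

    Deterministic for a fixed seed and library version (single-threaded
    exact layout). Requires at least ``n_neighbors + 1`` samples.
    """
    import umap  # deferred: numba compilation is slow at import

    X = np.asarray([np.asarray(f, dtype=float).ravel() for f in features])
    if len(X) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} samples, got {len(X)}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster(
    embedding: np.ndarray,
    min_cluster_size: int = 10,
    min_samples: int = 3,
    merge_threshold: float = 0.2,
) -> np.ndarray:
    """HDBSCAN labels on a 2-D embedding; -1 marks noise points.

    ``merge_threshold`` is the distance below which adjacent density peaks
    are merged into one cluster (cluster_selection_epsilon).
    """
    embedding = np.asarray(embedding, dtype=float)
    if len(embedding) == 0:
        raise ValueError("embedding is empty")
    if len(embedding) < min_cluster_size:
        return np.full(len(embedding), -1)
    model = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        cluster_selection_epsilon=merge_threshold,
    )
    return model.fit_predict(embedding)


@dataclass
class ClusterSummary:
    """Per-cluster population and averaged conformation."""

    cluster_id: int
    n_members: int
    population_fraction: float  # denominator counts noise points too
    mean_feature: np.ndarray
    reconstructed: Conformation
    end_to_end: float


def summarize_clusters(
    labels: np.ndarray,
    features: Sequence[np.ndarray],
    confs: Sequence[Conformation] | None = None,
) -> list[ClusterSummary]:
    """Population fractions and mean-feature reconstructions per cluster.

    Population fractions use all samples (noise included) as the
    denominator, so fractions over clusters plus the noise fraction sum
    to 1.
    """
    labels = np.asarray(labels)
    feats = [np.asarray(f, dtype=float) for f in features]
    if len(labels) != len(feats):
        raise ValueError("labels and features must be aligned")
    n_total = len(labels)
    out = []
    for cid in sorted(set(labels.tolist()) - {-1}):
        members = np.where(labels == cid)[0]
        mean_feat = np.mean([feats[i] for i in members], axis=0)
        rec = reconstruct(mean_feat)
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                n_members=len(members),
                population_fraction=len(members) / n_total,
                mean_feature=mean_feat,
                reconstructed=rec,
                end_to_end=end_to_end(rec),
            )
        )
    return out


@dataclass
class LandscapeResult:
    """Fitted conformational landscape.

    Attributes
    ----------
    embedding : (n, 2) UMAP coordinates, one point per conformation.
    labels : HDBSCAN cluster labels, -1 for noise.
    clusters : list of :class:`ClusterSummary`, sorted by cluster id.
    noise_fraction : fraction of points labelled noise.
    seed : the embedding seed used (recorded for reproducibility; layouts
        differ across library versions, so comparisons are within-run only).
    """

    embedding: np.ndarray
    labels: np.ndarray
    clusters: list[ClusterSummary]
    noise_fraction: float
    seed: int
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c.cluster_id,
                "n_members": c.n_members,
                "population_fraction": c.population_fraction,
                "end_to_end_A": c.end_to_end,
            }
            for c in self.clusters
        ]
        rows.append(
            {
                "cluster": -1,
                "n_members": int(np.sum(self.labels == -1)),
                "population_fraction": self.noise_fraction,
                "end_to_end_A": np.nan,
            }
        )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Scatter of the 2-D landscape coloured by cluster label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = ax.scatter(
            self.embedding[:, 0], self.embedding[:, 1], c=self.labels, s=8, cmap="tab10"
        )
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        ax.figure.colorbar(sc, ax=ax, label="cluster")
        return ax


class ConformationalLandscape:
    """Landscape model over a set of backbone conformations.

    Parameters mirror the pipeline defaults: UMAP with 15 neighbours and
    min_dist 0.0, HDBSCAN with minimum cluster size 10, 3 core-point
    neighbours and a 0.2 merge distance.
    """

    def __init__(
        self,
        confs: Sequence[Conformation],
        n_neighbors: int = 15,
        min_dist: float = 0.0,
        min_cluster_size: int = 10,
        min_samples: int = 3,
        merge_threshold: float = 0.2,
    ):
        self.confs = list(confs)
        self.features = [featurize(c) for c in self.confs]
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.merge_threshold = merge_threshold

    def fit(self, seed: int = 42) -> LandscapeResult:
        emb = embed(self.features, self.n_neighbors, self.min_dist, seed)
        labels = cluster(
            emb, self.min_cluster_size, self.min_samples, self.merge_threshold
        )
        summaries = summarize_clusters(labels, self.features, self.confs)
        return LandscapeResult(
            embedding=emb,
            labels=labels,
            clusters=summaries,
            noise_fraction=float(np.mean(labels == -1)),
            seed=seed,
            params={
                "n_neighbors": self.n_neighbors,
                "min_dist": self.min_dist,
                "min_cluster_size": self.min_cluster_size,
                "min_samples": self.min_samples,
                "merge_threshold": self.merge_threshold,
            },
        )
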