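"""Graph-based clustering of cell embeddings and the cluster hierarchy.

``snn_graph_cluster`` reproduces the standard single-cell clustering
contract: a k-nearest-neighbor graph on Euclidean distances in the
embedding, shared-nearest-neighbor (SNN) edge weights from neighborhood
Jaccard overlap with weak edges pruned, then Louvain modularity
optimization. ``cluster_goi_hierarchy`` groups the resulting clusters by
complete-link agglomeration on cosine similarity of their GOI
detection-rate profiles.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.neighbors import NearestNeighbors

from .data import ExpressionMatrix, ValidationError

DEFAULT_N_NEIGHBORS = 20
DEFAULT_RESOLUTION = 0.8
DEFAULT_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster ids in ``[0, k)`` (every id occupied)."""

    cell_ids: np.ndarray
    cluster_of: np.ndarray
    k: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.cell_ids) != len(self.cluster_of):
            raise ValidationError("cell_ids and cluster_of lengths differ")
        present = np.unique(self.cluster_of)
        if self.k != len(present) or (present != np.arange(self.k)).any():
            raise ValidationError("cluster ids must occupy [0, k) exactly")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of == cluster)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=self.k)


def _relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map labels to contiguous ids ordered by first appearance."""
    _, inv = np.unique(labels, return_inverse=True)
    order: dict[int, int] = {}
    out = np.empty_like(inv)
    for i, v in enumerate(inv):
        if v not in order:
            order[v] = len(order)
        out[i] = order[v]
    return out, len(order)


def snn_graph_cluster(
    embedding: np.ndarray,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    resolution: float = DEFAULT_RESOLUTION,
    seed: int = 0,
    prune: float = DEFAULT_PRUNE,
    cell_ids: np.ndarray | None = None,
    method: str = "louvain",
) -> ClusterAssignment:
    """SNN-graph community detection on an embedding.

    kNN by Euclidean distance (each cell's neighborhood includes itself),
    SNN edge weight = Jaccard overlap of the two neighborhoods, edges with
    weight <= ``prune`` dropped, then Louvain (default) or Leiden at the
    given resolution, seeded for reproducibility.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    m = embedding.shape[0]
    if m <= n_neighbors:
        raise ValidationError(
            f"need more cells ({m}) than n_neighbors ({n_neighbors})"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(embedding)
    knn = nn.kneighbors(embedding, return_distance=False)
    # neighborhood sets include the cell itself
    hoods = [set(row) | {i} for i, row in enumerate(knn)]

    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    for i in range(m):
        hi = hoods[i]
        for j in knn[i]:
            if j <= i:
                continue
            inter = len(hi & hoods[j])
            union = len(hi) + len(hoods[j]) - inter
            w = inter / union
            if w > prune:
                edges.append((i, int(j)))
                weights.append(w)

    graph = igraph.Graph(n=m, edges=edges)
    graph.es["weight"] = weights
    if method == "louvain":
        # igraph delegates its RNG to Python's random module
        rstate = _pyrandom.getstate()
        _pyrandom.seed(seed)
        try:
            part = graph.community_multilevel(
                weights="weight", resolution=resolution
            )
        finally:
            _pyrandom.setstate(rstate)
        labels = np.asarray(part.membership)
    elif method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        labels = np.asarray(part.membership)
    else:
        raise ValidationError(f"unknown clustering method {method!r}")

    labels, k = _relabel(labels)
    if cell_ids is None:
        cell_ids = np.array([f"cell_{i}" for i in range(m)], dtype=object)
    return ClusterAssignment(
        cell_ids=np.asarray(cell_ids, dtype=object),
        cluster_of=labels,
        k=k,
        params={
            "n_neighbors": n_neighbors,
            "resolution": resolution,
            "metric": "euclidean",
            "seed": seed,
            "prune": prune,
            "method": method,
        },
    )


def cluster_goi_hierarchy(
    X_lognorm: ExpressionMatrix,
    assignment: ClusterAssignment,
    goi_genes: list[str],
    n_groups: int,
) -> dict[int, int]:
    """Group clusters by complete-link agglomeration on GOI detection rates.

    Each cluster is summarized by its detection-rate vector over the GOI
    genes; the dissimilarity between clusters is 1 - cosine similarity.
    Clusters whose detection vector is all-zero cannot be placed on the
    cosine scale and are assigned singleton groups. Returns a mapping from
    cluster id to group label in ``[0, n_groups_effective)``.
    """
    from .evaluate import detection_rates

    if not goi_genes:
        raise ValidationError("need at least one GOI gene")
    rates = detection_rates(X_lognorm, assignment, goi_genes)  # genes x clusters
    vectors = rates.T  # clusters x genes
    norms = np.linalg.norm(vectors, axis=1)
    nonzero = np.flatnonzero(norms > 0)
    zero = np.flatnonzero(norms == 0)
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")

    mapping: dict[int, int] = {}
    n_eff = min(n_groups, len(nonzero)) if len(nonzero) else 0
    if len(nonzero) == 1:
        mapping[int(nonzero[0])] = 0
    elif len(nonzero) > 1:
        V = vectors[nonzero] / norms[nonzero, None]
        # condensed 1 - cosine similarity distances
        sim = np.clip(V @ V.T, -1.0, 1.0)
        dist = 1.0 - sim
        iu = np.triu_indices(len(nonzero), k=1)
        Z = linkage(dist[iu], method="complete")
        flat = fcluster(Z, t=n_eff, criterion="maxclust")
        # deterministic group labels: order groups by their smallest cluster id
        order: dict[int, int] = {}
        for cid, grp in sorted(zip(nonzero, flat)):
            if grp not in order:
                order[grp] = len(order)
            mapping[int(cid)] = order[grp]
    next_label = len(set(mapping.values()))
    for cid in zero:
        mapping[int(cid)] = next_label
        next_label += 1
    return mapping
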