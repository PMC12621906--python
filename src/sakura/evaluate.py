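"""Evaluation statistics for cell clusters and embeddings.

Three families of measures:

* **Distinctiveness** — a dot-plot-derived score of how cleanly on/off a
  gene's expression is across clusters. For gene *i* and cluster *j*,
  ``T_ij = q(t_ij)`` maps the detection rate through the quadratic
  ``q(t) = 4t(t-1) + 1`` (1 at rates 0 and 1, 0 at 0.5), and
  ``E_ij = q(F_i(e_ij))`` maps the ECDF of the cluster's mean expression.
  The overall score ``G`` averages ``T_ij * E_ij`` over clusters and genes
  and lies in [0, 1].
* **Internal validation** — Davies-Bouldin index, average silhouette width
  and Calinski-Harabasz index from the embedding geometry alone, under
  Euclidean or cosine distance.
* **External validation** — clusters are first labeled by the cell type
  occupying >= 50% of their cells (ties broken lexicographically; clusters
  with no majority become "unannotated"); per-type precision/recall/F1 are
  computed from cell proportions, plus ARI and NMI against the reference
  partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment
from .data import ExpressionMatrix, ValidationError

UNANNOTATED = "unannotated"
_COS_EPS = 1e-8


@dataclass
class EvaluationReport:
    """Keyed collection of named scalar measures with their conventions."""

    scalars: dict[str, float] = field(default_factory=dict)
    per_gene: dict[str, float] = field(default_factory=dict)
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scalars": self.scalars,
            "per_gene": self.per_gene,
            "per_type": self.per_type,
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# distinctiveness
# ---------------------------------------------------------------------------

def q(t: float) -> float:
    """Quadratic distinctiveness kernel ``4 t (t - 1) + 1`` on [0, 1]."""
    t = np.asarray(t, dtype=np.float64)
    if np.any((t < 0) | (t > 1)):
        raise ValidationError("q() argument must lie in [0, 1]")
    out = 4.0 * t * (t - 1.0) + 1.0
    return float(out) if out.ndim == 0 else out


def detection_rates(
    X_lognorm: ExpressionMatrix,
    assignment: ClusterAssignment,
    genes: list[str],
) -> np.ndarray:
    """``(genes, clusters)`` matrix of within-cluster nonzero fractions."""
    rates = np.empty((len(genes), assignment.k))
    sizes = assignment.sizes()
    for gi, gene in enumerate(genes):
        col = X_lognorm.gene_column(gene)
        nz = (col != 0).astype(np.float64)
        counts = np.bincount(assignment.cluster_of, weights=nz, minlength=assignment.k)
        rates[gi] = counts / sizes
    return rates


def _ecdf(values: np.ndarray):
    """Right-continuous ECDF with ties counted as <=: F(v) = #{x <= v}/M."""
    sorted_vals = np.sort(values)
    m = len(values)

    def F(v):
        return np.searchsorted(sorted_vals, v, side="right") / m

    return F


def distinctiveness(
    X_lognorm: ExpressionMatrix,
    assignment: ClusterAssignment,
    genes: list[str],
    mean_mode: str = "all_cells",
) -> tuple[dict[str, float], float]:
    """Per-gene distinctiveness scores and their unweighted mean G.

    ``mean_mode="all_cells"`` (default) averages a gene over all cells of a
    cluster; ``"expressing_only"`` averages over expressing cells only (the
    dot-plot convention), falling back to ``F_i(0)`` when no cell expresses.
    """
    if not genes:
        raise ValidationError("need at least one gene")
    if mean_mode not in ("all_cells", "expressing_only"):
        raise ValidationError(f"unknown mean_mode {mean_mode!r}")
    rates = detection_rates(X_lognorm, assignment, genes)
    per_gene: dict[str, float] = {}
    for gi, gene in enumerate(genes):
        col = X_lognorm.gene_column(gene)
        F = _ecdf(col)
        scores = np.empty(assignment.k)
        for j in range(assignment.k):
            members = assignment.members(j)
            vals = col[members]
            T = q(rates[gi, j])
            if mean_mode == "all_cells":
                e = vals.mean()
            else:
                expressing = vals[vals != 0]
                e = expressing.mean() if len(expressing) else 0.0
            E = q(F(e))
            scores[j] = T * E
        per_gene[gene] = float(scores.mean())
    G = float(np.mean(list(per_gene.values())))
    return per_gene, G


# ---------------------------------------------------------------------------
# distances / internal validation
# ---------------------------------------------------------------------------

def _pairwise(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        return cdist(A, B, metric="euclidean")
    if metric == "cosine":
        na = np.linalg.norm(A, axis=1) + _COS_EPS
        nb = np.linalg.norm(B, axis=1) + _COS_EPS
        return 1.0 - (A @ B.T) / np.outer(na, nb)
    raise ValidationError(f"unknown metric {metric!r}")


def _centroids(embedding: np.ndarray, assignment: ClusterAssignment) -> np.ndarray:
    cents = np.empty((assignment.k, embedding.shape[1]))
    for x in range(assignment.k):
        cents[x] = embedding[assignment.members(x)].mean(axis=0)
    return cents


def davies_bouldin(
    embedding: np.ndarray, assignment: ClusterAssignment, metric: str = "euclidean"
) -> float:
    """Mean over clusters of the worst compactness-to-separation ratio.

    ``R_xy = (S_x + S_y) / d(centroid_x, centroid_y)`` with ``S_x`` the mean
    member-to-centroid distance; DBI is the mean of ``max_{y != x} R_xy``.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    k = assignment.k
    if k < 2:
        raise ValidationError("DBI requires at least 2 clusters")
    cents = _centroids(embedding, assignment)
    S = np.empty(k)
    for x in range(k):
        members = assignment.members(x)
        S[x] = _pairwise(embedding[members], cents[x:x + 1], metric).mean()
    D = _pairwise(cents, cents, metric)
    if np.any(D[~np.eye(k, dtype=bool)] == 0):
        raise ValidationError("coincident cluster centroids (zero separation)")
    R = (S[:, None] + S[None, :]) / np.where(D > 0, D, np.inf)
    np.fill_diagonal(R, -np.inf)
    return float(R.max(axis=1).mean())


def silhouette(
    embedding: np.ndarray, assignment: ClusterAssignment, metric: str = "euclidean"
) -> float:
    """Average silhouette width in [-1, 1].

    ``a_i`` is the mean distance to same-cluster cells, ``b_i`` the smallest
    mean distance to another cluster, ``s_i = (b_i - a_i)/max(a_i, b_i)``;
    singleton clusters contribute ``s_i = 0``.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    k = assignment.k
    if k < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    n = embedding.shape[0]
    D = _pairwise(embedding, embedding, metric)
    sizes = assignment.sizes()
    labels = assignment.cluster_of
    # sum of distances from each cell to each cluster
    sums = np.zeros((n, k))
    for x in range(k):
        sums[:, x] = D[:, labels == x].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        x = labels[i]
        if sizes[x] == 1:
            continue  # singleton convention
        a = sums[i, x] / (sizes[x] - 1)
        others = [sums[i, y] / sizes[y] for y in range(k) if y != x]
        b = min(others)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def calinski_harabasz(
    embedding: np.ndarray, assignment: ClusterAssignment, metric: str = "euclidean"
) -> float:
    """Between-to-within dispersion ratio, normalized by (n-k)/(k-1)."""
    embedding = np.asarray(embedding, dtype=np.float64)
    k = assignment.k
    n = embedding.shape[0]
    if k < 2 or n <= k:
        raise ValidationError("CHI requires 2 <= k < n")
    cents = _centroids(embedding, assignment)
    overall = embedding.mean(axis=0, keepdims=True)
    sizes = assignment.sizes()
    between = float(
        (sizes * _pairwise(cents, overall, metric).ravel() ** 2).sum()
    )
    within = 0.0
    for x in range(k):
        members = assignment.members(x)
        within += float(
            (_pairwise(embedding[members], cents[x:x + 1], metric).ravel() ** 2).sum()
        )
    if within == 0:
        raise ValidationError("zero within-cluster scatter")
    return (n - k) / (k - 1) * between / within


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def _is_missing(label) -> bool:
    return label is None or (isinstance(label, float) and np.isnan(label)) or label == ""


def label_clusters(
    assignment: ClusterAssignment, reference: np.ndarray
) -> dict[int, str]:
    """Label each cluster by the cell type holding >= 50% of its cells.

    Cells with missing reference labels count toward cluster size but can
    never name a cluster. Exact 50% qualifies; a 50/50 tie between two
    types goes to the lexicographically smaller type name. Clusters with no
    qualifying type are labeled ``"unannotated"``.
    """
    reference = np.asarray(reference, dtype=object)
    if len(reference) != len(assignment.cluster_of):
        raise ValidationError("reference length != number of cells")
    out: dict[int, str] = {}
    for x in range(assignment.k):
        members = assignment.members(x)
        counts: dict[str, int] = {}
        for lab in reference[members]:
            if not _is_missing(lab):
                counts[str(lab)] = counts.get(str(lab), 0) + 1
        size = len(members)
        qualifying = sorted(
            (t for t, c in counts.items() if c / size >= 0.5),
            key=lambda t: (-counts[t], t),
        )
        out[x] = qualifying[0] if qualifying else UNANNOTATED
    return out


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Pair-counting ARI of two partitions of the same cells."""
    table = _contingency(np.asarray(a), np.asarray(b))
    n = table.sum()
    sum_comb = (table * (table - 1) // 2).sum()
    arow = table.sum(axis=1)
    bcol = table.sum(axis=0)
    comb_a = (arow * (arow - 1) // 2).sum()
    comb_b = (bcol * (bcol - 1) // 2).sum()
    total = n * (n - 1) // 2
    expected = comb_a * comb_b / total if total else 0.0
    max_index = (comb_a + comb_b) / 2.0
    if max_index == expected:
        return 1.0 if sum_comb == max_index else 0.0
    return float((sum_comb - expected) / (max_index - expected))


def normalized_mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """NMI = 2 MI / (H(a) + H(b)) with natural logs.

    When both partitions are trivial (zero entropy) the value is 1 if the
    partitions are identical as set partitions, else 0.
    """
    table = _contingency(np.asarray(a), np.asarray(b)).astype(np.float64)
    n = table.sum()
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    ha = -np.sum(px * np.log(px, where=px > 0, out=np.zeros_like(px)))
    hb = -np.sum(py * np.log(py, where=py > 0, out=np.zeros_like(py)))
    if ha + hb == 0:
        return 1.0 if table.shape == (1, 1) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pxy > 0, pxy / np.outer(px, py), 1.0)
        mi = np.sum(pxy * np.log(ratio))
    return float(2.0 * mi / (ha + hb))


def external_scores(
    assignment: ClusterAssignment, reference: np.ndarray
) -> EvaluationReport:
    """Per-type precision/recall/F1 plus ARI and NMI against a reference.

    Cells with missing reference labels are excluded from all proportions
    (and from the ARI/NMI contingency).
    """
    reference = np.asarray(reference, dtype=object)
    cluster_labels = label_clusters(assignment, reference)
    cell_cluster_label = np.array(
        [cluster_labels[c] for c in assignment.cluster_of], dtype=object
    )
    known = np.array([not _is_missing(r) for r in reference])
    ref_known = np.array([str(r) for r in reference[known]], dtype=object)
    pred_known = cell_cluster_label[known]
    n_known = known.sum()

    report = EvaluationReport(
        metadata={"labeling_rule": ">=50% majority, ties lexicographic",
                  "missing_reference": "excluded"}
    )
    for ctype in sorted(set(ref_known)):
        is_type = ref_known == ctype
        in_labeled = pred_known == ctype
        tp = float(np.sum(is_type & in_labeled)) / n_known
        fp = float(np.sum(~is_type & in_labeled)) / n_known
        fn = float(np.sum(is_type & ~in_labeled)) / n_known
        tn = float(np.sum(~is_type & ~in_labeled)) / n_known
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        report.per_type[ctype] = {
            "TP": tp, "FP": fp, "TN": tn, "FN": fn,
            "precision": precision, "recall": recall, "f1": f1,
        }
    clusters_known = assignment.cluster_of[known]
    report.scalars["ARI"] = adjusted_rand_index(clusters_known, ref_known)
    report.scalars["NMI"] = normalized_mutual_info(clusters_known, ref_known)
    if report.per_type:
        report.scalars["mean_f1"] = float(
            np.mean([v["f1"] for v in report.per_type.values()])
        )
    return report


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

def build_report(
    embedding: np.ndarray,
    assignment: ClusterAssignment,
    X_lognorm: ExpressionMatrix | None = None,
    goi_genes: list[str] | None = None,
    reference: np.ndarray | None = None,
    metric: str = "euclidean",
    mean_mode: str = "all_cells",
) -> EvaluationReport:
    """Compute every applicable measure into one report."""
    report = EvaluationReport(metadata={"metric": metric})
    if assignment.k >= 2:
        report.scalars["DBI"] = davies_bouldin(embedding, assignment, metric)
        report.scalars["ASW"] = silhouette(embedding, assignment, metric)
        report.scalars["CHI"] = calinski_harabasz(embedding, assignment, metric)
    if X_lognorm is not None and goi_genes:
        per_gene, G = distinctiveness(X_lognorm, assignment, goi_genes, mean_mode)
        report.per_gene.update(per_gene)
        report.scalars["distinctiveness_G"] = G
    if reference is not None:
        ext = external_scores(assignment, reference)
        report.scalars.update(ext.scalars)
        report.per_type.update(ext.per_type)
    return report
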