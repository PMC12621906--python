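"""Evaluation-measure tests: closed forms, hand-walks, and brute-force oracles."""

import numpy as np
import pytest

from sakura.cluster import ClusterAssignment
from sakura.data import ExpressionMatrix, ValidationError
from sakura.evaluate import (
    adjusted_rand_index,
    calinski_harabasz,
    davies_bouldin,
    detection_rates,
    distinctiveness,
    external_scores,
    label_clusters,
    normalized_mutual_info,
    q,
    silhouette,
)


def assign(labels):
    labels = np.asarray(labels)
    return ClusterAssignment(
        cell_ids=np.array([f"c{i}" for i in range(len(labels))], dtype=object),
        cluster_of=labels,
        k=int(labels.max()) + 1,
    )


def lognorm_matrix(values):
    return ExpressionMatrix(np.asarray(values, dtype=float), layer_tag="lognorm")


# ---------------------------------------------------------------------------
# quadratic kernel and detection rates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("t,expected", [(0.0, 1.0), (0.5, 0.0), (1.0, 1.0),
                                        (0.25, 0.25), (0.75, 0.25)])
def test_q_closed_form(t, expected):
    assert q(t) == pytest.approx(expected)


def test_q_rejects_out_of_range():
    with pytest.raises(ValidationError):
        q(1.5)


def test_detection_rates_counting():
    X = lognorm_matrix([[0.0], [1.0], [2.0], [0.0]])
    a = assign([0, 0, 0, 1])
    rates = detection_rates(X, a, ["gene_0"])
    assert rates[0, 0] == pytest.approx(2 / 3)
    assert rates[0, 1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# distinctiveness
# ---------------------------------------------------------------------------

def test_distinctiveness_hand_walk():
    """4 cells in 2 equal clusters; gene at 2.0 in cluster A, 0 in B -> G=0.5."""
    X = lognorm_matrix([[2.0], [2.0], [0.0], [0.0]])
    a = assign([0, 0, 1, 1])
    per_gene, G = distinctiveness(X, a, ["gene_0"])
    assert G == pytest.approx(0.5)
    assert per_gene["gene_0"] == pytest.approx(0.5)


def test_distinctiveness_constant_gene_single_cluster():
    X = lognorm_matrix([[3.0], [3.0], [3.0]])
    a = assign([0, 0, 0])
    _, G = distinctiveness(X, a, ["gene_0"])
    assert G == pytest.approx(1.0)


def test_distinctiveness_range_random(rng):
    X = lognorm_matrix(np.abs(rng.normal(size=(40, 3))))
    a = assign(rng.integers(0, 4, size=40))
    a = assign(np.unique(a.cluster_of, return_inverse=True)[1])
    _, G = distinctiveness(X, a, list(X.gene_ids))
    assert 0.0 <= G <= 1.0


def test_distinctiveness_invariant_to_cluster_split(rng):
    """Splitting a cluster into identical halves leaves every score unchanged."""
    vals = np.abs(rng.normal(size=(24, 2)))
    vals[rng.random(vals.shape) < 0.4] = 0.0
    X = lognorm_matrix(np.vstack([vals, vals]))
    merged = assign([0] * 24 + [0] * 24)
    # same cells, but the duplicated copy forms its own (identical) cluster
    split = assign([0] * 24 + [1] * 24)
    genes = list(X.gene_ids)
    _, G_merged = distinctiveness(X, merged, genes)
    _, G_split = distinctiveness(X, split, genes)
    assert G_split == pytest.approx(G_merged, abs=0.0)


def test_distinctiveness_relabel_and_duplicate_invariance(rng):
    vals = np.abs(rng.normal(size=(30, 2)))
    X = lognorm_matrix(vals)
    labels = rng.integers(0, 3, size=30)
    labels = np.unique(labels, return_inverse=True)[1]
    genes = list(X.gene_ids)
    _, G = distinctiveness(X, assign(labels), genes)
    # relabel clusters
    perm = np.array([2, 0, 1])
    _, G_relabel = distinctiveness(X, assign(perm[labels]), genes)
    assert G_relabel == pytest.approx(G)
    # duplicate every cell
    X2 = ExpressionMatrix(np.vstack([vals, vals]), layer_tag="lognorm")
    _, G_dup = distinctiveness(X2, assign(np.concatenate([labels, labels])), genes)
    assert G_dup == pytest.approx(G)


# ---------------------------------------------------------------------------
# internal validation: hand values
# ---------------------------------------------------------------------------

def test_dbi_hand_value():
    emb = np.array([[0.0], [2.0], [10.0], [12.0]])
    a = assign([0, 0, 1, 1])
    assert davies_bouldin(emb, a) == pytest.approx(0.2)


def test_dbi_singletons_zero():
    emb = np.array([[0.0], [5.0]])
    a = assign([0, 1])
    assert davies_bouldin(emb, a) == pytest.approx(0.0)


def test_dbi_coincident_centroids_error():
    emb = np.array([[0.0], [2.0], [0.0], [2.0]])
    a = assign([0, 0, 1, 1])
    with pytest.raises(ValidationError):
        davies_bouldin(emb, a)


def test_asw_hand_value():
    emb = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    a = assign([0, 0, 1, 1])
    b = (10.0 + np.sqrt(101.0)) / 2.0
    expected = (b - 1.0) / b
    assert silhouette(emb, a) == pytest.approx(expected, abs=1e-9)
    assert silhouette(emb, a) == pytest.approx(0.9002, abs=5e-5)


def test_chi_hand_value():
    emb = np.array([[0.0], [2.0], [10.0], [12.0]])
    a = assign([0, 0, 1, 1])
    assert calinski_harabasz(emb, a) == pytest.approx(50.0)


def test_chi_scale_invariance(rng):
    emb = rng.normal(size=(20, 3))
    labels = np.r_[np.zeros(10, int), np.ones(10, int)]
    a = assign(labels)
    assert calinski_harabasz(emb * 7.3, a) == pytest.approx(
        calinski_harabasz(emb, a)
    )


# ---------------------------------------------------------------------------
# oracle equivalence on random instances
# ---------------------------------------------------------------------------

def brute_dbi(emb, labels):
    k = labels.max() + 1
    cents = np.array([emb[labels == x].mean(axis=0) for x in range(k)])
    S = np.array([
        np.mean([np.linalg.norm(p - cents[x]) for p in emb[labels == x]])
        for x in range(k)
    ])
    worst = []
    for x in range(k):
        worst.append(max(
            (S[x] + S[y]) / np.linalg.norm(cents[x] - cents[y])
            for y in range(k) if y != x
        ))
    return float(np.mean(worst))


def brute_asw(emb, labels):
    n = len(labels)
    k = labels.max() + 1
    s = []
    for i in range(n):
        x = labels[i]
        same = [j for j in range(n) if labels[j] == x and j != i]
        if not same:
            s.append(0.0)
            continue
        a = np.mean([np.linalg.norm(emb[i] - emb[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(emb[i] - emb[j])
                     for j in range(n) if labels[j] == y])
            for y in range(k) if y != x
        )
        s.append((b - a) / max(a, b))
    return float(np.mean(s))


def brute_chi(emb, labels):
    n = len(labels)
    k = labels.max() + 1
    overall = emb.mean(axis=0)
    cents = np.array([emb[labels == x].mean(axis=0) for x in range(k)])
    sizes = np.bincount(labels)
    between = sum(sizes[x] * np.linalg.norm(cents[x] - overall) ** 2 for x in range(k))
    within = sum(
        np.linalg.norm(emb[i] - cents[labels[i]]) ** 2 for i in range(n)
    )
    return (n - k) / (k - 1) * between / within


def brute_ari(a, b):
    n = len(a)
    same_a = np.equal.outer(a, a)
    same_b = np.equal.outer(b, b)
    iu = np.triu_indices(n, 1)
    s11 = np.sum(same_a[iu] & same_b[iu])
    s00 = np.sum(~same_a[iu] & ~same_b[iu])
    total = len(iu[0])
    ri = (s11 + s00) / total
    # expected RI from marginals
    pairs_a = np.sum(same_a[iu])
    pairs_b = np.sum(same_b[iu])
    exp_s11 = pairs_a * pairs_b / total
    exp_ri = (exp_s11 + (total - pairs_a - pairs_b + exp_s11)) / total
    max_ri = ((pairs_a + pairs_b) / 2 + (total - pairs_a) + (total - pairs_b)
              - (total - pairs_a - pairs_b + exp_s11) * 0) / total
    # use standard pair-count identity instead of the max derivation above
    num = s11 - exp_s11
    den = (pairs_a + pairs_b) / 2 - exp_s11
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return num / den


@pytest.mark.parametrize("trial", range(20))
def test_internal_measures_match_oracles(trial):
    """DBI/ASW/CHI agree with O(n^2)/O(k^2) brute-force implementations."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(10, 50))
    k = int(rng.integers(2, 5))
    emb = rng.normal(size=(n, int(rng.integers(2, 6))))
    labels = rng.integers(0, k, size=n)
    labels[:k] = np.arange(k)  # every cluster occupied
    labels = np.unique(labels, return_inverse=True)[1]
    a = assign(labels)
    assert davies_bouldin(emb, a) == pytest.approx(brute_dbi(emb, labels), abs=1e-9)
    assert silhouette(emb, a) == pytest.approx(brute_asw(emb, labels), abs=1e-9)
    assert calinski_harabasz(emb, a) == pytest.approx(brute_chi(emb, labels), abs=1e-9)


@pytest.mark.parametrize("trial", range(20))
def test_internal_measures_match_sklearn(trial):
    """Cross-check against scikit-learn's independent implementations."""
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    rng = np.random.default_rng(2000 + trial)
    n = int(rng.integers(12, 50))
    emb = rng.normal(size=(n, 3))
    labels = rng.integers(0, 3, size=n)
    labels[:3] = np.arange(3)
    labels = np.unique(labels, return_inverse=True)[1]
    a = assign(labels)
    assert davies_bouldin(emb, a) == pytest.approx(
        davies_bouldin_score(emb, labels), abs=1e-9
    )
    assert silhouette(emb, a) == pytest.approx(
        silhouette_score(emb, labels), abs=1e-9
    )
    assert calinski_harabasz(emb, a) == pytest.approx(
        calinski_harabasz_score(emb, labels), abs=1e-9
    )


@pytest.mark.parametrize("trial", range(20))
def test_ari_nmi_match_oracles(trial):
    from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

    rng = np.random.default_rng(3000 + trial)
    n = int(rng.integers(10, 50))
    a = rng.integers(0, 4, size=n)
    b = rng.integers(0, 3, size=n)
    assert adjusted_rand_index(a, b) == pytest.approx(
        adjusted_rand_score(a, b), abs=1e-9
    )
    assert adjusted_rand_index(a, b) == pytest.approx(brute_ari(a, b), abs=1e-9)
    assert normalized_mutual_info(a, b) == pytest.approx(
        normalized_mutual_info_score(a, b), abs=1e-9
    )


def test_ari_trivial_partition_is_zero():
    assert adjusted_rand_index(
        np.array([0, 0, 0, 0]), np.array(["A", "A", "B", "B"])
    ) == pytest.approx(0.0)


def test_ari_random_partitions_mean_near_zero():
    rng = np.random.default_rng(99)
    vals = [
        adjusted_rand_index(rng.integers(0, 5, 100), rng.integers(0, 5, 100))
        for _ in range(200)
    ]
    assert abs(np.mean(vals)) < 0.02


# ---------------------------------------------------------------------------
# cluster labeling and external scores
# ---------------------------------------------------------------------------

def test_label_clusters_majority_and_ties():
    a = assign([0] * 5 + [1] * 5 + [2] * 4)
    ref = np.array(
        ["A", "A", "A", "B", "C"]          # cluster 0: 60% A
        + ["A", "A", "B", "B", "C"]        # cluster 1: no majority
        + ["B", "B", "A", "A"],            # cluster 2: 50/50 tie -> "A"
        dtype=object,
    )
    labels = label_clusters(a, ref)
    assert labels[0] == "A"
    assert labels[1] == "unannotated"
    assert labels[2] == "A"


def test_external_scores_perfect_agreement():
    a = assign([0, 0, 1, 1, 2, 2])
    ref = np.array(["x", "x", "y", "y", "z", "z"], dtype=object)
    report = external_scores(a, ref)
    assert report.scalars["ARI"] == pytest.approx(1.0)
    assert report.scalars["NMI"] == pytest.approx(1.0)
    for stats in report.per_type.values():
        assert stats["f1"] == pytest.approx(1.0)


def test_external_scores_permutation_invariance(rng):
    labels = rng.integers(0, 3, size=30)
    labels = np.unique(labels, return_inverse=True)[1]
    ref = np.array(list("ABC"))[rng.integers(0, 3, size=30)].astype(object)
    r1 = external_scores(assign(labels), ref)
    perm = np.array([1, 2, 0])
    r2 = external_scores(assign(perm[labels]), ref)
    assert r1.scalars["ARI"] == pytest.approx(r2.scalars["ARI"])
    assert r1.scalars["NMI"] == pytest.approx(r2.scalars["NMI"])
    for t in r1.per_type:
        assert r1.per_type[t]["f1"] == pytest.approx(r2.per_type[t]["f1"])
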