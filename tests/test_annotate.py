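"""Annotation-refinement tests: single-GOI calls, QC filter, rule table,
signature scores."""

import numpy as np
import pandas as pd
import pytest

from sakura.annotate import (
    RefinementConfig,
    combine_doublet_votes,
    qc_pass,
    refine_annotations,
    signature_cooccurrence,
    signature_scores,
    single_goi_clusters,
)
from sakura.cluster import ClusterAssignment
from sakura.data import ExpressionMatrix, ValidationError
from sakura.simulate import make_fixture


def detection_fixture(vectors, cells_per=10):
    vectors = np.asarray(vectors, float)
    k, g = vectors.shape
    blocks, labels = [], []
    for c in range(k):
        block = np.zeros((cells_per, g))
        for j in range(g):
            block[: int(round(vectors[c, j] * cells_per)), j] = 1.0
        blocks.append(block)
        labels.extend([c] * cells_per)
    X = ExpressionMatrix(np.vstack(blocks), layer_tag="lognorm")
    a = ClusterAssignment(cell_ids=X.cell_ids, cluster_of=np.array(labels), k=k)
    return X, a


# ---------------------------------------------------------------------------
# single-GOI calls
# ---------------------------------------------------------------------------

def test_single_goi_detection_rules():
    X, a = detection_fixture([
        [0.9, 0.0, 0.1, 0.0, 0.0],   # single-GOI: gene_0
        [0.9, 0.6, 0.0, 0.0, 0.0],   # two expressed -> multi
        [0.1, 0.1, 0.1, 0.0, 0.0],   # nothing expressed
    ])
    out = single_goi_clusters(X, a, list(X.gene_ids), hi_thresh=0.5, lo_thresh=0.1)
    assert out[0] == ["gene_0"]
    assert set(out[1]) == {"gene_0", "gene_1"}
    assert out[2] == []


def test_single_goi_intermediate_detection_disqualifies():
    # second gene between lo and hi: not single even though only one >= hi
    X, a = detection_fixture([[0.9, 0.3, 0.0, 0.0, 0.0]])
    out = single_goi_clusters(X, a, list(X.gene_ids), 0.5, 0.1)
    assert set(out[0]) == {"gene_0", "gene_1"}


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_table(umis, votes=None):
    umis = np.asarray(umis)
    n = len(umis)
    votes = np.zeros(n, int) if votes is None else np.asarray(votes)
    # reads and gene counts co-vary with UMIs so the UMI rule decides
    return pd.DataFrame({
        "total_reads": umis * 100,
        "total_umi": umis,
        "n_genes": umis * 10,
        "doublet_votes": votes,
    })


def test_qc_percentile_ladder():
    qc = qc_table(np.arange(1, 11))
    ok = qc_pass(qc, percentile=30.0)
    # nearest-rank 30th percentile of 1..10 is 3; cells with umi <= 3 fail
    np.testing.assert_array_equal(ok, np.arange(1, 11) > 3)


def test_qc_conjunction_over_metrics():
    qc = qc_table(np.arange(1, 11))
    qc.loc[9, "n_genes"] = 0.0  # best umi but worst gene count
    ok = qc_pass(qc, percentile=30.0)
    assert not ok[9]


def test_qc_zero_percentile_passes_all():
    qc = qc_table(np.arange(1, 6))
    assert qc_pass(qc, percentile=0.0).all()


def test_qc_thresholds_from_non_doublets_only():
    # doublets have tiny values; excluding them moves thresholds up
    umis = np.r_[np.arange(10, 20), [1, 1]]
    votes = np.r_[np.zeros(10, int), [2, 3]]
    ok = qc_pass(qc_table(umis, votes), percentile=30.0)
    threshold = np.sort(umis[:10])[2]  # rank ceil(0.3*10)=3 -> value 12
    np.testing.assert_array_equal(ok, umis > threshold)


def test_qc_monotone_in_percentile(rng):
    qc = qc_table(rng.integers(1, 1000, size=50))
    passed = [qc_pass(qc, p).sum() for p in (0, 10, 30, 50, 80)]
    assert passed == sorted(passed, reverse=True)


def test_combine_doublet_votes():
    a = np.array([True, False, True])
    b = np.array([False, False, True])
    c = np.array([True, False, True])
    np.testing.assert_array_equal(combine_doublet_votes(a, b, c), [2, 0, 3])


# ---------------------------------------------------------------------------
# the refinement rule table on the packaged toy fixture
# ---------------------------------------------------------------------------

EXPECTED_TOY_ACTIONS = {
    # cluster 0 (single-GOI HORM1, 70% broad): broad cells -> subtype,
    # acinar cell -> suspicious, clean unlabeled -> new subtype,
    # unlabeled doublet -> unchanged
    "T00": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T01": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T02": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T03": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T04": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T05": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T06": ("broad_to_subtype", "islet endocrine cells:HORM1"),
    "T07": ("suspicious", None),
    "T08": ("new_subtype", "islet endocrine cells:HORM1"),
    "T09": ("unchanged", None),
    # cluster 1 (two GOI genes expressed, 60% broad): no subtype promotion;
    # acinar cells -> suspicious; clean unlabeled -> broad label only;
    # unlabeled doublet -> unchanged
    "T10": ("unchanged", None),
    "T11": ("unchanged", None),
    "T12": ("unchanged", None),
    "T13": ("unchanged", None),
    "T14": ("unchanged", None),
    "T15": ("unchanged", None),
    "T16": ("suspicious", None),
    "T17": ("suspicious", None),
    "T18": ("new_subtype", "islet endocrine cells"),
    "T19": ("unchanged", None),
}


@pytest.fixture(scope="module")
def toy():
    from sakura.preprocess import log_normalize

    X, clusters, meta, truth = make_fixture("annotation_toy")
    ln = log_normalize(X)
    a = ClusterAssignment(cell_ids=X.cell_ids, cluster_of=clusters,
                          k=int(clusters.max()) + 1)
    return ln, a, meta


def test_refine_annotations_hand_table(toy):
    ln, a, meta = toy
    out = refine_annotations(ln, a, ["HORM1", "HORM2"], meta,
                             "islet endocrine cells")
    got = {row.cell_id: (row.action, row.assigned_label)
           for row in out.itertuples()}
    assert got == EXPECTED_TOY_ACTIONS


def test_refine_annotations_bit_stable(toy):
    ln, a, meta = toy
    r1 = refine_annotations(ln, a, ["HORM1", "HORM2"], meta,
                            "islet endocrine cells")
    r2 = refine_annotations(ln, a, ["HORM1", "HORM2"], meta,
                            "islet endocrine cells")
    pd.testing.assert_frame_equal(r1, r2)


def test_refine_no_cell_both_new_and_suspicious(toy):
    ln, a, meta = toy
    out = refine_annotations(ln, a, ["HORM1", "HORM2"], meta,
                             "islet endocrine cells")
    assert not ((out.action == "new_subtype") & (out.action == "suspicious")).any()


def test_refine_promotion_monotone_in_percentile(toy):
    ln, a, meta = toy
    counts = []
    for p in (0.0, 30.0, 60.0, 90.0):
        out = refine_annotations(ln, a, ["HORM1", "HORM2"], meta,
                                 "islet endocrine cells",
                                 RefinementConfig(qc_percentile=p))
        counts.append((out.action == "new_subtype").sum())
    assert counts == sorted(counts, reverse=True)


def test_refine_missing_broad_label_errors(toy):
    ln, a, meta = toy
    with pytest.raises(ValidationError):
        refine_annotations(ln, a, ["HORM1"], meta, "no such label")


# ---------------------------------------------------------------------------
# signature scores
# ---------------------------------------------------------------------------

def test_signature_single_gene_is_zscore():
    vals = np.array([[0.0], [1.0], [2.0]])
    X = ExpressionMatrix(vals, gene_ids=np.array(["g"], dtype=object),
                         layer_tag="lognorm")
    out = signature_scores(X, {"s": ["g"]})
    z = (vals[:, 0] - 1.0) / np.std(vals[:, 0])
    np.testing.assert_allclose(out["s"], z, atol=1e-12)


def test_signature_hand_values():
    vals = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    X = ExpressionMatrix(vals, layer_tag="lognorm")
    out = signature_scores(X, {"s": ["gene_0", "gene_1"]})
    np.testing.assert_allclose(
        out["s"], [-1.22474487, 0.0, 1.22474487], atol=1e-8
    )


def test_signature_constant_errors():
    X = ExpressionMatrix(np.ones((4, 1)), layer_tag="lognorm")
    with pytest.raises(ValidationError):
        signature_scores(X, {"s": ["gene_0"]})


def test_signature_top_decile_and_cooccurrence(rng):
    vals = np.abs(rng.normal(size=(100, 4)))
    X = ExpressionMatrix(vals, layer_tag="lognorm")
    out = signature_scores(X, {"a": ["gene_0", "gene_1"], "b": ["gene_2"]})
    assert out["a_top"].sum() == 10
    co = signature_cooccurrence(out)
    assert co.loc["a", "a"] == 10
    assert co.loc["a", "b"] == (out["a_top"] & out["b_top"]).sum()
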