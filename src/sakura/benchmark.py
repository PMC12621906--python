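"""Desk-scale benchmark protocol on the packaged rare-subtype fixture.

Runs the full pipeline — simulate, preprocess, train, embed, cluster,
evaluate — for the knowledge-guided model and the PCA-50 baseline under
identical clustering settings, and reports rare-subtype separation (ARI
restricted to the subtype's parent compartment, mirroring the protocol of
evaluating CD4+/CD8+ separation within T cells), marker-gene
distinctiveness, and the over-supervision silhouette signal.

Desk-scale settings (hidden widths 32, batches 50/25, 200 epochs) follow
the capacity-scaling principle of the underlying method — network width and
batch size scale with data size; the bottleneck stays at 50 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import snn_graph_cluster
from .evaluate import adjusted_rand_index, distinctiveness, silhouette
from .model import GOISpec, GOITarget, ModelConfig, build_goi_targets
from .preprocess import log_normalize, pca_embed, scale_genes
from .simulate import make_fixture
from .train import TrainConfig, canary_check, embed_all, fit

FIXTURE_SEED = 7
BENCH_EPOCHS = 200
BENCH_WIDTHS = (32, 32, 32)
BENCH_BATCHES = (50, 25)  # rec, goi
OVERSUP_MULTIPLIER = 1000.0


@dataclass
class BenchmarkResult:
    """Per-seed pipeline outputs of one benchmark run."""

    seed: int
    pca_ari_subtype: float
    model_ari_subtype: float
    pca_G: float
    model_G: float
    oversup_asw: float
    pca_k: int
    model_k: int
    oversup_k: int
    canary: dict = field(default_factory=dict)


def _prepare(fixture_seed: int = FIXTURE_SEED):
    (X, truth), params = make_fixture("rare_subtype", seed=fixture_seed)
    ln = log_normalize(X)
    sc = scale_genes(ln)
    labels = truth["true_population"].to_numpy()
    marker_ids = [str(X.gene_ids[g]) for g in params.marker_genes["C_rare"]]
    spec = GOISpec([GOITarget(g, "gene", (g,)) for g in marker_ids])
    targets = build_goi_targets(ln, spec)
    return ln, sc, labels, marker_ids, spec, targets


def run_rare_subtype_benchmark(
    seeds: tuple[int, ...] = (0, 1, 2),
    epochs: int = BENCH_EPOCHS,
    fixture_seed: int = FIXTURE_SEED,
    include_oversupervised: bool = True,
) -> list[BenchmarkResult]:
    """Train per seed and compare against the PCA-50 baseline.

    The subtype ARI is computed over cells of the rare subtype's parent
    population only (labels C vs C_rare), i.e. how well the clustering
    resolves the subtype from its parent.
    """
    ln, sc, labels, marker_ids, spec, targets = _prepare(fixture_seed)
    Xs = sc.dense()
    pca = pca_embed(sc, 50)
    parent = (labels == "C") | (labels == "C_rare")
    model_config = ModelConfig(input_dim=Xs.shape[1], hidden_widths=BENCH_WIDTHS)

    results = []
    for seed in seeds:
        a_pca = snn_graph_cluster(pca, seed=seed)
        _, G_pca = distinctiveness(ln, a_pca, marker_ids)

        cfg = TrainConfig(epochs=epochs, seed=seed,
                          batch_rec=BENCH_BATCHES[0], batch_goi=BENCH_BATCHES[1])
        state = fit(Xs, targets, cfg, model_config, spec)
        emb = embed_all(state.model, Xs)
        a_model = snn_graph_cluster(emb, seed=seed)
        _, G_model = distinctiveness(ln, a_model, marker_ids)
        canary = canary_check(state, emb[state.train_idx], emb[state.test_idx],
                              seed=seed)

        oversup_asw = float("nan")
        oversup_k = 0
        if include_oversupervised:
            cfg_over = TrainConfig(
                epochs=epochs, seed=seed,
                batch_rec=BENCH_BATCHES[0], batch_goi=BENCH_BATCHES[1],
                goi_multiplier=OVERSUP_MULTIPLIER,
            )
            state_over = fit(Xs, targets, cfg_over, model_config, spec)
            emb_over = embed_all(state_over.model, Xs)
            a_over = snn_graph_cluster(emb_over, seed=seed)
            oversup_asw = silhouette(emb_over, a_over)
            oversup_k = a_over.k

        results.append(BenchmarkResult(
            seed=seed,
            pca_ari_subtype=adjusted_rand_index(
                a_pca.cluster_of[parent], labels[parent]
            ),
            model_ari_subtype=adjusted_rand_index(
                a_model.cluster_of[parent], labels[parent]
            ),
            pca_G=G_pca,
            model_G=G_model,
            oversup_asw=oversup_asw,
            pca_k=a_pca.k,
            model_k=a_model.k,
            oversup_k=oversup_k,
            canary=canary,
        ))
    return results


def summarize(results: list[BenchmarkResult]) -> dict[str, float]:
    med = lambda xs: float(np.median(xs))
    return {
        "pca_ari_subtype_median": med([r.pca_ari_subtype for r in results]),
        "model_ari_subtype_median": med([r.model_ari_subtype for r in results]),
        "pca_G_median": med([r.pca_G for r in results]),
        "model_G_median": med([r.model_G for r in results]),
        "oversup_asw_median": med([r.oversup_asw for r in results]),
    }
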