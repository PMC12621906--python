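"""Robustness harness: gene-list variants and supervision-intensity sweeps.

Trains the model over a grid of (GOI-list variant, intensity multiplier,
seed), clusters and evaluates each embedding, and collects all internal and
external measures into one tidy table. A negative average silhouette width
flags over-supervision (excessive GOI weight distorting the embedding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import snn_graph_cluster
from .data import ExpressionMatrix
from .evaluate import build_report
from .model import GOISpec, ModelConfig, build_goi_targets
from .train import TrainConfig, embed_all, fit


@dataclass
class SweepSpec:
    gene_lists: dict[str, GOISpec]
    intensity_multipliers: list[float] = field(default_factory=lambda: [1.0])
    seeds: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if not self.gene_lists or not self.seeds:
            raise ValueError("need at least one gene-list variant and one seed")


def run_sweep(
    X_scaled: np.ndarray,
    X_lognorm: ExpressionMatrix,
    reference: np.ndarray,
    sweep: SweepSpec,
    base_config: TrainConfig,
    model_config: ModelConfig | None = None,
    cluster_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Train/cluster/evaluate every (variant, multiplier, seed) combination."""
    cluster_kwargs = dict(cluster_kwargs or {})
    rows = []
    for list_name, spec in sweep.gene_lists.items():
        targets = build_goi_targets(X_lognorm, spec) if len(spec) else None
        for mult in sweep.intensity_multipliers:
            for seed in sweep.seeds:
                cfg = replace(
                    base_config, seed=seed, goi_multiplier=mult,
                    use_goi=mult > 0 and targets is not None,
                )
                state = fit(X_scaled, targets, cfg, model_config, goi_spec=spec)
                embedding = embed_all(state.model, X_scaled)
                ck = dict(cluster_kwargs)
                ck.setdefault("seed", seed)
                assignment = snn_graph_cluster(embedding, **ck)
                report = build_report(
                    embedding, assignment,
                    X_lognorm=X_lognorm, goi_genes=spec.all_genes() or None,
                    reference=reference,
                )
                row = {
                    "gene_list": list_name,
                    "multiplier": mult,
                    "seed": seed,
                    "n_clusters": assignment.k,
                    **report.scalars,
                }
                row["over_supervised"] = bool(row.get("ASW", 0.0) < 0)
                rows.append(row)
    return pd.DataFrame(rows)
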