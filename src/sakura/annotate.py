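"""Knowledge-guided annotation refinement.

Given clusters from the knowledge-guided embedding, marker (GOI) detection
rates, per-cell QC metrics, external doublet votes and the original
author annotations, these procedures (1) promote clean, high-quality
unannotated cells inside marker-expressing clusters to specific subtype
labels, and (2) flag cells whose existing annotation disagrees with the
marker expression of their cluster as suspicious (without asserting the
original annotation is wrong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .data import ExpressionMatrix, ValidationError
from .evaluate import detection_rates

DEFAULT_HI_THRESH = 0.5
DEFAULT_LO_THRESH = 0.1
DEFAULT_QC_PERCENTILE = 30.0

QC_METRICS = ("total_reads", "total_umi", "n_genes")

ACTION_NEW = "new_subtype"
ACTION_BROAD = "broad_to_subtype"
ACTION_SUSPICIOUS = "suspicious"
ACTION_UNCHANGED = "unchanged"


def combine_doublet_votes(*flags: np.ndarray) -> np.ndarray:
    """Sum up to three boolean doublet calls into a per-cell vote count."""
    if not 1 <= len(flags) <= 3:
        raise ValidationError("expected 1-3 doublet flag columns")
    votes = np.sum([np.asarray(f, dtype=bool).astype(int) for f in flags], axis=0)
    return votes


def single_goi_clusters(
    X_lognorm: ExpressionMatrix,
    assignment: ClusterAssignment,
    goi_genes: list[str],
    hi_thresh: float = DEFAULT_HI_THRESH,
    lo_thresh: float = DEFAULT_LO_THRESH,
) -> dict[int, list[str]]:
    """Which GOI genes each cluster "expresses", with single-GOI calls.

    A gene is expressed in a cluster when its detection rate >= ``hi_thresh``.
    Returns the expressed-gene list per cluster; a cluster is single-GOI
    (exactly one expressed gene and every other gene's detection
    <= ``lo_thresh``) iff its list has length one — intermediate detection
    of a second gene disqualifies it, in which case the list keeps all
    genes above ``lo_thresh``.
    """
    rates = detection_rates(X_lognorm, assignment, goi_genes)
    out: dict[int, list[str]] = {}
    for j in range(assignment.k):
        col = rates[:, j]
        expressed = [goi_genes[i] for i in range(len(goi_genes)) if col[i] >= hi_thresh]
        if len(expressed) == 1:
            others = [col[i] for i in range(len(goi_genes))
                      if goi_genes[i] != expressed[0]]
            if all(r <= lo_thresh for r in others):
                out[j] = expressed
                continue
        # not a clean single-GOI cluster: report every gene above lo_thresh
        out[j] = [goi_genes[i] for i in range(len(goi_genes)) if col[i] > lo_thresh]
    return out


def qc_pass(qc: pd.DataFrame, percentile: float = DEFAULT_QC_PERCENTILE) -> np.ndarray:
    """Per-cell QC filter against non-doublet percentile thresholds.

    For each of the three metrics the threshold is the nearest-rank
    ``percentile`` over non-doublet cells only; a cell passes iff all three
    of its values are strictly above their thresholds. ``percentile <= 0``
    passes every cell.
    """
    for col in QC_METRICS:
        if col not in qc.columns:
            raise ValidationError(f"QC table missing column {col!r}")
    votes = qc["doublet_votes"].to_numpy() if "doublet_votes" in qc.columns else (
        np.zeros(len(qc), dtype=int)
    )
    clean = votes == 0
    if not clean.any():
        raise ValidationError("no non-doublet cells to compute QC thresholds")
    ok = np.ones(len(qc), dtype=bool)
    if percentile <= 0:
        return ok
    for col in QC_METRICS:
        vals = qc[col].to_numpy(dtype=np.float64)
        ref = np.sort(vals[clean])
        rank = math.ceil(percentile / 100.0 * len(ref))
        threshold = ref[max(rank - 1, 0)]
        ok &= vals > threshold
    return ok


@dataclass
class RefinementConfig:
    hi_thresh: float = DEFAULT_HI_THRESH
    lo_thresh: float = DEFAULT_LO_THRESH
    qc_percentile: float = DEFAULT_QC_PERCENTILE
    subtype_of: dict[str, str] | None = None  # GOI gene -> subtype label


def refine_annotations(
    X_lognorm: ExpressionMatrix,
    assignment: ClusterAssignment,
    goi_genes: list[str],
    meta: pd.DataFrame,
    broad_label: str,
    config: RefinementConfig | None = None,
) -> pd.DataFrame:
    """Annotation-refinement rules applied per cell.

    1. Restrict to clusters composed of > 50% cells carrying the broad
       prior label.
    2. Unlabeled cells there with zero doublet votes that pass the QC
       percentile filter provisionally receive the broad label
       (action ``new_subtype`` once rule 3 applies, else stays provisional
       broad assignment).
    3. Any broad-labeled cell (original or provisional) in a single-GOI
       cluster is assigned that gene's subtype label.
    4. Cells in GOI-expressing clusters whose prior label differs from the
       broad label are flagged ``suspicious``.

    ``meta`` must carry ``cell_id``, ``prior_label`` (empty/NaN for
    unlabeled), the three QC metric columns and ``doublet_votes``.
    Returns a table with columns cell_id, action, assigned_label, reasons.
    """
    config = config or RefinementConfig()
    meta = meta.set_index("cell_id").loc[list(assignment.cell_ids)].reset_index()
    prior = meta["prior_label"].to_numpy(dtype=object)
    prior = np.array(
        [None if (p is None or (isinstance(p, float) and np.isnan(p)) or p == "")
         else str(p) for p in prior], dtype=object,
    )
    if broad_label not in set(p for p in prior if p is not None):
        raise ValidationError(f"broad label {broad_label!r} absent from priors")
    votes = meta["doublet_votes"].to_numpy(dtype=int)
    passes = qc_pass(meta, config.qc_percentile)

    expressed = single_goi_clusters(
        X_lognorm, assignment, goi_genes, config.hi_thresh, config.lo_thresh
    )
    rates = detection_rates(X_lognorm, assignment, goi_genes)
    single_clusters = set()
    for x in range(assignment.k):
        col = rates[:, x]
        above = col >= config.hi_thresh
        if above.sum() == 1 and np.all(col[~above] <= config.lo_thresh):
            single_clusters.add(x)
    subtype_of = config.subtype_of or {g: f"{broad_label}:{g}" for g in goi_genes}

    # rule 1: clusters > 50% broad-labeled
    broad_clusters = set()
    for x in range(assignment.k):
        members = assignment.members(x)
        frac = np.mean([prior[i] == broad_label for i in members])
        if frac > 0.5:
            broad_clusters.add(x)

    n = len(prior)
    action = np.array([ACTION_UNCHANGED] * n, dtype=object)
    assigned = np.array([None] * n, dtype=object)
    reasons: list[list[str]] = [[] for _ in range(n)]

    for i in range(n):
        x = assignment.cluster_of[i]
        genes_here = expressed.get(x, [])
        is_single = x in single_clusters
        in_goi_cluster = len(genes_here) >= 1

        # rule 4: conflicting prior label in a GOI-expressing cluster
        if in_goi_cluster and prior[i] is not None and prior[i] != broad_label:
            action[i] = ACTION_SUSPICIOUS
            reasons[i].append("prior_label_conflicts_with_goi_cluster")
            continue

        if x not in broad_clusters:
            continue

        effective_broad = prior[i] == broad_label
        newly_promoted = False
        if prior[i] is None:
            if votes[i] == 0 and passes[i]:
                effective_broad = True
                newly_promoted = True
                reasons[i].append("clean_unlabeled_in_broad_cluster")
            else:
                if votes[i] > 0:
                    reasons[i].append("doublet_votes")
                if not passes[i]:
                    reasons[i].append("qc_fail")
                continue

        # rule 3: subtype assignment in single-GOI clusters
        if effective_broad and is_single:
            assigned[i] = subtype_of[genes_here[0]]
            action[i] = ACTION_NEW if newly_promoted else ACTION_BROAD
            reasons[i].append(f"single_goi_cluster:{genes_here[0]}")
        elif newly_promoted:
            assigned[i] = broad_label
            action[i] = ACTION_NEW
            reasons[i].append("broad_label_assigned")

    return pd.DataFrame({
        "cell_id": assignment.cell_ids,
        "action": action,
        "assigned_label": assigned,
        "reasons": [";".join(r) for r in reasons],
    })


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def signature_scores(
    X_lognorm: ExpressionMatrix,
    signatures: dict[str, list[str]],
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-cell signature scores with top-decile flags.

    Each score is the z-score (population s.d.) across cells of the
    per-cell mean of z-scored member gene columns. ``<name>_top`` flags the
    cells whose score falls in the top ``top_fraction`` of all cells.
    """
    if X_lognorm.layer_tag != "lognorm":
        raise ValidationError("signature scores are computed on lognorm data")
    out = {"cell_id": X_lognorm.cell_ids}
    for name, genes in signatures.items():
        if not genes:
            raise ValidationError(f"signature {name!r} is empty")
        zcols = []
        for g in genes:
            col = X_lognorm.gene_column(g)
            sd = col.std()
            if sd > 0:
                zcols.append((col - col.mean()) / sd)
        if not zcols:
            raise ValidationError(f"signature {name!r} has only constant genes")
        avg = np.mean(zcols, axis=0)
        sd = avg.std()
        score = (avg - avg.mean()) / sd if sd > 0 else np.zeros_like(avg)
        out[name] = score
        cutoff = np.quantile(score, 1.0 - top_fraction)
        out[f"{name}_top"] = score >= cutoff
    return pd.DataFrame(out)


def signature_cooccurrence(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise counts of cells flagged in the top decile of two signatures."""
    flag_cols = [c for c in scores.columns if c.endswith("_top")]
    names = [c[:-4] for c in flag_cols]
    table = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(flag_cols):
        for j, b in enumerate(flag_cols):
            table[i, j] = int((scores[a] & scores[b]).sum())
    return pd.DataFrame(table, index=names, columns=names)
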