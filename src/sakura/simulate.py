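"""Synthetic scRNA-seq count generator.

Emulates the data regime the embedding method targets: a few major cell
populations, a rare subpopulation that shares its parent's expression
profile except for a handful of marker genes, lognormal library sizes,
negative-binomial counts, and optional doublet-like and unlabeled cells.
Counts are drawn with the counter-based Philox bit generator so fixtures
are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import ExpressionMatrix, ValidationError


@dataclass
class Population:
    name: str
    fraction: float
    parent: str | None = None


@dataclass
class SimulationParams:
    """Parameters of the generative model.

    Per cell: a population is drawn by the stated fractions and a library
    size from a lognormal; per gene the rate is proportional to
    ``exp(base_log_mean + LFC)`` normalized across genes and scaled to the
    library size; counts are negative binomial with dispersion ``r``
    (variance ``mu + mu^2 / r``). Doublets average two random cells' rate
    vectors and resample. A ``unlabeled_rate`` fraction of cells have their
    labels hidden in the truth table (but retained as ``true_*`` columns).
    """

    n_cells: int = 2000
    n_genes: int = 1000
    populations: list[Population] = field(default_factory=list)
    base_log_mean: float = 0.0
    log_fold_changes: dict[tuple[str, int], float] = field(default_factory=dict)
    marker_genes: dict[str, list[int]] = field(default_factory=dict)
    dispersion: float = 2.0
    library_size_log_mean: float = np.log(5000.0)
    library_size_log_sd: float = 0.25
    dropout_midpoint: float | None = None
    dropout_slope: float = 1.0
    doublet_rate: float = 0.0
    unlabeled_rate: float = 0.0
    # continuum gene programs (cell-cycle-like gradients shared by all
    # cells): each program couples `program_genes` random genes through a
    # per-cell N(0,1) activity scaled by loadings ~ N(0, program_loading_sd)
    n_programs: int = 0
    program_genes: int = 30
    program_loading_sd: float = 0.4
    seed: int = 0
    poisson_limit: bool = False  # dispersion -> infinity (pure Poisson)

    def __post_init__(self) -> None:
        if not self.populations:
            self.populations = [Population("pop0", 1.0)]
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"population fractions sum to {total}, not 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not (0 <= self.doublet_rate < 1):
            raise ValidationError("doublet_rate must lie in [0, 1)")
        if not (0 <= self.unlabeled_rate < 1):
            raise ValidationError("unlabeled_rate must lie in [0, 1)")
        for pop, genes in self.marker_genes.items():
            if any(g < 0 or g >= self.n_genes for g in genes):
                raise ValidationError(f"marker gene index out of range for {pop!r}")


def _population_rates(params: SimulationParams) -> dict[str, np.ndarray]:
    """Relative expression profile (sums to 1) per population."""
    log_mu = {
        p.name: np.full(params.n_genes, params.base_log_mean)
        for p in params.populations
    }
    # children start from their parent's profile
    for p in params.populations:
        if p.parent is not None:
            if p.parent not in log_mu:
                raise ValidationError(f"unknown parent population {p.parent!r}")
    for (pop, gene), lfc in params.log_fold_changes.items():
        if pop not in log_mu:
            raise ValidationError(f"unknown population {pop!r} in log_fold_changes")
    # apply parent LFCs first, then the population's own
    resolved = {}
    for p in params.populations:
        base = np.full(params.n_genes, params.base_log_mean)
        chain = []
        cur = p
        while cur is not None:
            chain.append(cur.name)
            cur = next(
                (q for q in params.populations if q.name == cur.parent), None
            )
        for name in reversed(chain):
            for (pop, gene), lfc in params.log_fold_changes.items():
                if pop == name:
                    base[gene] += lfc
        mu = np.exp(base)
        resolved[p.name] = mu / mu.sum()
    return resolved


def simulate_counts(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a raw count matrix and its truth table."""
    rng = np.random.Generator(np.random.Philox(params.seed))
    profiles = _population_rates(params)
    names = [p.name for p in params.populations]
    fractions = np.array([p.fraction for p in params.populations])

    pop_idx = rng.choice(len(names), size=params.n_cells, p=fractions)
    lib = np.exp(
        rng.normal(params.library_size_log_mean, params.library_size_log_sd,
                   size=params.n_cells)
    )
    rel = np.stack([profiles[names[i]] for i in pop_idx])
    if params.n_programs:
        # loadings and gene sets are a fixed function of the seed; activities
        # vary per cell, adding smooth within-type heterogeneity
        prg = np.random.Generator(np.random.Philox([params.seed, 77]))
        loadings = np.zeros((params.n_programs, params.n_genes))
        for p in range(params.n_programs):
            genes = prg.choice(params.n_genes, size=params.program_genes,
                               replace=False)
            loadings[p, genes] = prg.normal(0.0, params.program_loading_sd,
                                            size=params.program_genes)
        activity = rng.normal(size=(params.n_cells, params.n_programs))
        rel = rel * np.exp(activity @ loadings)
        rel /= rel.sum(axis=1, keepdims=True)
    rates = rel * lib[:, None]

    n_doublets = int(round(params.doublet_rate * params.n_cells))
    is_doublet = np.zeros(params.n_cells, dtype=bool)
    if n_doublets:
        which = rng.choice(params.n_cells, size=n_doublets, replace=False)
        partners = rng.integers(0, params.n_cells, size=n_doublets)
        rates[which] = 0.5 * (rates[which] + rates[partners])
        is_doublet[which] = True

    if params.dropout_midpoint is not None:
        with np.errstate(divide="ignore"):
            logmu = np.log(np.maximum(rates, 1e-12))
        p_drop = 1.0 / (1.0 + np.exp(
            params.dropout_slope * (logmu - params.dropout_midpoint)
        ))
        keep = rng.random(rates.shape) >= p_drop
        rates = rates * keep

    if params.poisson_limit:
        counts = rng.poisson(rates)
    else:
        r = params.dispersion
        # NB as Gamma-Poisson mixture: mean mu, variance mu + mu^2 / r
        lam = rng.gamma(shape=r, scale=rates / r)
        counts = rng.poisson(lam)

    pop_names = np.array([names[i] for i in pop_idx], dtype=object)
    parents = {p.name: p.parent for p in params.populations}
    major = np.array(
        [parents[nm] if parents[nm] is not None else nm for nm in pop_names],
        dtype=object,
    )
    hidden = rng.random(params.n_cells) < params.unlabeled_rate
    visible = np.where(hidden, None, pop_names)

    X = ExpressionMatrix(
        sp.csr_matrix(counts.astype(np.float64)),
        gene_ids=np.array([f"G{j:04d}" for j in range(params.n_genes)], dtype=object),
        cell_ids=np.array([f"C{i:05d}" for i in range(params.n_cells)], dtype=object),
        layer_tag="raw",
    )
    truth = pd.DataFrame({
        "cell_id": X.cell_ids,
        "population": visible,
        "true_population": pop_names,
        "major_type": major,
        "is_doublet": is_doublet,
        "library_size": lib,
    })
    return X, truth


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "rare_subtype", "two_similar_subtypes", "senescence_scores", "annotation_toy"
)


def make_fixture(name: str, seed: int = 7):
    """Deterministic desk-scale scenarios used throughout the test suite.

    * ``rare_subtype`` — 2,000 cells x 1,000 genes; major types A/B/C at
      40/30/25% separable by 50 moderately shifted genes each, plus a 5%
      subtype of C distinguished only by 5 marker genes at LFC 2.
    * ``two_similar_subtypes`` — two 50/50 populations differing in 5
      markers only.
    * ``senescence_scores`` — two gene signatures jointly elevated in 5% of
      cells.
    * ``annotation_toy`` — a 20-cell hand-checkable annotation scenario
      (built directly, not sampled; see tests).
    """
    if name not in FIXTURE_NAMES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    rng = np.random.Generator(np.random.Philox([seed, 1234]))
    if name == "rare_subtype":
        n_genes = 1000
        lfc: dict[tuple[str, int], float] = {}
        used: set[int] = set()
        # major types differ broadly (easy for any embedding method), the
        # rare subtype only in its 5 markers
        for pop in ("A", "B", "C"):
            genes = rng.choice(
                [g for g in range(n_genes) if g not in used], size=100, replace=False
            )
            used.update(int(g) for g in genes)
            for g in genes:
                lfc[(pop, int(g))] = float(rng.choice([-1.5, 1.5]))
        markers = [int(g) for g in rng.choice(
            [g for g in range(n_genes) if g not in used], size=5, replace=False
        )]
        for g in markers:
            # marker genes behave like hormone genes: near-off in every
            # major type, strongly on in the rare subtype (near-binary
            # detection, the regime knowledge-guided embedding targets)
            for pop in ("A", "B", "C"):
                lfc[(pop, g)] = -4.0
            lfc[("C_rare", g)] = 4.0
        params = SimulationParams(
            n_cells=2000,
            n_genes=n_genes,
            populations=[
                Population("A", 0.40), Population("B", 0.30),
                Population("C", 0.25), Population("C_rare", 0.05, parent="C"),
            ],
            log_fold_changes=lfc,
            marker_genes={"C_rare": markers},
            n_programs=80,
            program_loading_sd=0.8,
            seed=seed,
        )
        return simulate_counts(params), params
    if name == "two_similar_subtypes":
        n_genes = 500
        markers = list(range(5))
        lfc: dict[tuple[str, int], float] = {("S1", g): -3.0 for g in markers}
        lfc.update({("S2", g): 2.0 for g in markers})
        params = SimulationParams(
            n_cells=1000, n_genes=n_genes,
            populations=[Population("S1", 0.5), Population("S2", 0.5, parent="S1")],
            log_fold_changes=lfc, marker_genes={"S2": markers}, seed=seed,
        )
        return simulate_counts(params), params
    if name == "senescence_scores":
        n_genes = 400
        sig_a = list(range(0, 7))       # CDK-inhibitor-like signature
        sig_b = list(range(10, 30))     # aging-signature-like set
        lfc = {("SEN", g): 1.5 for g in sig_a + sig_b}
        params = SimulationParams(
            n_cells=1000, n_genes=n_genes,
            populations=[Population("BG", 0.95), Population("SEN", 0.05, parent="BG")],
            log_fold_changes=lfc,
            marker_genes={"SEN": sig_a + sig_b},
            seed=seed,
        )
        return simulate_counts(params), params
    # annotation_toy: deterministic hand-built 20-cell scenario
    return _annotation_toy()


def _annotation_toy():
    """20 cells, 2 clusters, 2 marker genes: a hand-checkable refinement case.

    Cluster 0 (cells 0-9) expresses only gene HORM1 (single-GOI, 90%
    detection); 7 cells carry the broad prior label, one carries "acinar",
    two are unlabeled (one clean and QC-good, one a doublet). Cluster 1
    (cells 10-19) expresses both markers (not single-GOI) and is mixed.
    """
    n = 20
    genes = np.array(["HORM1", "HORM2", "OTHER"], dtype=object)
    counts = np.zeros((n, 3))
    counts[0:9, 0] = 5.0          # cluster 0: HORM1 in 9/10 cells
    counts[9, 0] = 0.0
    counts[:, 2] = 1.0            # housekeeping so no empty cells
    counts[10:20, 0] = 4.0        # cluster 1 expresses both hormones
    counts[10:20, 1] = 4.0
    X = ExpressionMatrix(
        counts,
        gene_ids=genes,
        cell_ids=np.array([f"T{i:02d}" for i in range(n)], dtype=object),
        layer_tag="raw",
    )
    clusters = np.array([0] * 10 + [1] * 10)
    prior = np.array(
        ["islet endocrine cells"] * 7 + ["acinar cells"] + [None, None]
        + ["islet endocrine cells"] * 6 + ["acinar cells"] * 2 + [None, None],
        dtype=object,
    )
    doublets = np.zeros(n, dtype=int)
    doublets[9] = 2       # unlabeled doublet in cluster 0
    doublets[19] = 1      # unlabeled doublet in cluster 1
    # QC ladder: cell 8 (clean unlabeled) is given strong QC so it passes
    reads = 1000 + 100 * np.arange(n)
    umis = 500 + 50 * np.arange(n)
    ngenes = 100 + 10 * np.arange(n)
    meta = pd.DataFrame({
        "cell_id": X.cell_ids,
        "prior_label": prior,
        "total_reads": reads,
        "total_umi": umis,
        "n_genes": ngenes,
        "doublet_votes": doublets,
    })
    truth = pd.DataFrame({"cell_id": X.cell_ids, "cluster": clusters})
    return X, clusters, meta, truth
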