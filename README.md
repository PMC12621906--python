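# sakura

Knowledge-guided dimensionality reduction for single-cell transcriptomics.

Unsupervised embeddings (PCA, autoencoders) capture the dominant variation
in an expression matrix — which is exactly why they miss what a biologist
may care about most: a rare subtype defined by a handful of marker genes
whose variance is negligible next to cell-cycle gradients and major-type
differences. `sakura` embeds cells with a regularized autoencoder whose
50-dimensional bottleneck is additionally asked, through a small regression
head, to predict the expression of user-supplied **genes of interest**
(GOI). The embedding then retains marker information that variance-driven
methods discard, so downstream clustering can resolve the rare population.

The loss is `L = L_rec + L_reg + L_goi`:

* `L_rec = Σ_i λ₁‖x_i − x_i′‖₁ + λ₂‖x_i − x_i′‖₂²` — reconstruction
  through an encoder/decoder of three CELU hidden layers per side;
* `L_reg = λ₃·SW2(f_enc(D), P)` — sliced 2-Wasserstein distance between the
  embedding and a uniform prior `P = U(−k, k)^d`, preventing collapse;
* `L_goi = Σ_i λ₄‖y_i − ŷ_i‖₁ + λ₅‖y_i − ŷ_i‖₂² + λ₆(1 − cos(y_i, ŷ_i))`
  — regression of the GOI targets from the bottleneck.

λ₃ ramps from 1e-4 by 0.01/epoch; λ₄–λ₆ ramp from 0 by 0.01/epoch starting
at epoch 50 (all capped at 1), so the model learns general structure before
attending to the knowledge input. GOI targets can be single genes, sums of
genes (`CD8A + CD8B`), or the per-cell minimum of z-scored signature
averages (e.g. combining a CDK-inhibitor score with an aging-gene score).

The package also ships the surrounding toolkit: the standard preprocessing
recipe and PCA-50 baseline, SNN-graph Louvain clustering, a full evaluation
suite (gene-expression **distinctiveness**, DBI/ASW/CHI internal
validation, majority-vote cluster labeling with precision/recall/F1, ARI,
NMI), marker-driven annotation refinement (promoting clean unlabeled cells
to subtype labels, flagging suspicious annotations), gene-signature
scoring, a robustness sweep harness, and a negative-binomial simulator so
everything is testable offline.

## Worked example

The packaged benchmark simulates the regime described above — 2,000 cells,
1,000 genes, three major types plus a 5 % subtype distinguished only by 5
near-binary marker genes, with 80 continuum gene programs occupying the
top-50 PC spectrum — then trains the model (markers as GOI) and compares it
with PCA-50 under identical Louvain clustering:

```python
from sakura.benchmark import run_rare_subtype_benchmark, summarize
results = run_rare_subtype_benchmark(seeds=(0, 1, 2))
print(summarize(results))
```

```
{'pca_ari_subtype_median': 0.014, 'model_ari_subtype_median': 0.239,
 'pca_G_median': 0.563, 'model_G_median': 0.579,
 'oversup_asw_median': -0.007}
```

Reading: within the rare subtype's parent population, clustering the
PCA-50 embedding separates subtype from parent no better than chance
(ARI 0.014 — the markers rank below the top 50 principal directions), while
clustering the knowledge-guided embedding resolves it (ARI 0.239, median of
3 seeds). The marker genes are also more distinctively expressed across the
model's clusters (distinctiveness G 0.579 vs 0.563; G ranges 0–1 and
rewards clean on/off detection and extreme mean expression per cluster).
Multiplying the GOI weights by 1000 over-supervises: the embedding distorts
until the average silhouette width of its own clusters goes negative
(−0.007), the documented warning signal.

The same pipeline is scriptable from the shell:

```bash
sakura simulate --fixture rare_subtype --seed 7 --out sim/
sakura preprocess --input sim/matrix.mtx --n-hvg 1000 --goi goi.txt --out prep.h5
sakura train --input prep.h5 --goi goi.txt --seed 0 --out model.ckpt
sakura embed --input prep.h5 --model model.ckpt --out emb.csv
sakura cluster --embedding emb.csv --out clusters.tsv
sakura evaluate --embedding emb.csv --clusters clusters.tsv \
    --input prep.h5 --goi goi.txt --out report.json
sakura annotate --input prep.h5 --clusters clusters.tsv --meta meta.tsv \
    --goi goi.txt --broad-label "islet endocrine cells" --out annots.tsv
```

`goi.txt` holds one directive per line: `gene INS`, `sum CD8 = CD8A + CD8B`,
or `minz SEN = [Cdkn1a, Cdkn2a] ; [aging genes…]`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main computation from scratch: it simulates the
rare-subtype scenario, trains the knowledge-guided model at normal and
over-supervised intensity for three seeds derived from `--seed`, clusters
and evaluates both it and the PCA-50 baseline, runs the annotation-toy
refinement, prints the per-seed comparisons, and writes the results JSON.
Runtime is a few minutes on one CPU.
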