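# metasig

Discovery and validation of compact gene-expression signatures that separate
primary from metastatic tumors, with the surrounding statistics a
tumor-biomarker study needs: DEG-list intersection, PCA-loading signature
pruning, stepwise-AIC logistic stratification with threshold transfer across
cohorts, Kaplan–Meier / log-rank / Cox survival association, and GSEA-style
enrichment — plus a seeded synthetic-cohort generator so the whole path is
testable without any data download.

## Who this is for

Computational biologists who have (a) a candidate gene panel — e.g. the
intersection of transcription-factor-proximal differentially expressed genes
with knockdown DEGs — and (b) a bulk expression cohort (genes × samples,
log2 scale) with primary/metastatic annotations, and who want a small,
transferable signature plus honest estimates of how well it stratifies,
predicts outcome and enriches.

## The core algorithm

Given a standardized matrix (each gene z-scored to mean 0, sd 1) PCA is fit
with samples as observations. Let `v_k` be the loading vector of component
`k` and `VE_k` its variance-explained fraction ("first component value" =
`VE_1`). The signature search:

1. pick the component among the first `k_max` (default 3) whose scores best
   separate the two classes (largest |Welch *t*|);
2. pre-select the `k` genes with the most extreme |loading| on it
   (default `⌈panel/2⌉`);
3. backward-eliminate: refit PCA on the current panel, tentatively remove
   the gene with the smallest |loading| on PC1, and accept the removal iff
   `VE_1` does not drop (within `ε = 1e-6`) **and** the class separation of
   the PC1 scores does not drop by more than a 1% relative slack in
   |Welch *t*|; on rejection try the next-smallest candidate, stop when no
   gene is removable.

The surviving panel is the signature. Downstream, a logistic model
`logit P(metastatic) = β₀ + Σ β_g x_g` over signature genes is pruned by
bidirectional stepwise AIC, its probability threshold is chosen to maximize
balanced accuracy `(sensitivity + specificity)/2`, and the frozen model +
threshold are evaluated unchanged on independent cohorts.

## Worked example

```python
from metasig import (hotpam_like_config, simulate_expression_cohort,
                     standardize_genes, discover_signature)

study = simulate_expression_cohort(hotpam_like_config(seed=0))
std = standardize_genes(study.expression)
signature, report = discover_signature(std, study.annotation, study.signature_panel())
```

Running `examples/02_discover_signature.py` (which is exactly this) prints:

```
discovered signature: ['KIN1', 'KIN2', 'KIN3', 'KIN4', 'KIN7', 'SUPP1']
first-component variance share: 41.1%
separation: |t| = 35.1, AUC = 1.000
recovered 6/9 planted genes, 0 noise genes retained
```

The generator planted 9 informative genes (7 up-shifted, 2 down-shifted by
2 within-class sd) among 78 noise genes in a 194-primary / 29-metastatic
cohort; discovery recovered a pure subset of them whose first principal
component carries 41% of the panel variance and separates the classes
perfectly in-sample. Across 10 seeds the mean planted-gene recall is 0.87
with at most 3 noise genes retained. `examples/03_train_classifier.py`
continues to classification: a 4-gene stepwise model reaches balanced
accuracy 100% on its training cohort and 99.7% on an independently
generated one.

The other scripts in `examples/` walk each capability: cohort simulation,
classifier transfer, survival association (log-rank + Cox backward
selection), enrichment (NES by phenotype permutation, hypergeometric
over-representation) and the end-to-end pipeline with persisted artifacts.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's full pipeline from scratch at the given seed —
synthetic cohort generation, DEG-list intersection, signature discovery,
classifier training, cross-cohort evaluation, survival and enrichment — and
writes the acceptance JSON to `--out`.

## Layout

```
src/metasig/
  data_model.py   containers, TSV I/O, quantile normalization, z-scoring, DEGs
  stats_core.py   Fisher exact, Welch t, Wilcoxon, correlation, BH adjustment
  intersect.py    gene-list intersection and direction concordance
  signature.py    PCA, separating component, extreme loadings, greedy pruning
  classify.py     logistic fits, stepwise AIC, ROC, thresholds, transfer
  survival.py     KM, log-rank, Cox (Efron ties), backward selection
  enrichment.py   signal-to-noise ranking, weighted-KS ES/NES, GMT, ORA
  simulate.py     seeded synthetic cohorts, DEG lists, survival, clinical tables
  pipeline.py     end-to-end orchestration with persisted JSON/TSV artifacts
```

See `docs/methods.md` for the statistical conventions, default parameters
and known limitations.
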