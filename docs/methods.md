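# Methods

This note records the statistical model behind each stage, the defaults and
why they are set where they are, what the synthetic generator does and does
not emulate, and the numerical conventions a user relying on exact
reproducibility should know.

## Data model and normalizations

Expression matrices are genes × samples on the log2 scale, strictly finite;
loaders reject missing cells by default (optional per-gene mean imputation).
Duplicate gene rows collapse to the row with the highest mean expression,
the common microarray probe-collapse rule.

**Quantile normalization** forces every sample column onto the distribution
of per-rank cross-sample means. Ties within a column receive the mean of the
reference values across the spanned ranks. The operation is idempotent and
requires ≥ 2 samples.

**Gene standardization** z-scores each row with the *sample* standard
deviation (n−1 denominator, the convention of common statistical software).
Constant rows are dropped with a warning rather than zero-filled: a zero row
is undefined under z-scoring and contributes nothing to PCA loadings.
Cohorts are standardized independently (within-cohort) before discovery and
transfer; nothing in the pipeline assumes a shared scale across cohorts
beyond this.

**Differential expression** is per-gene Welch *t* on log2 values;
`log2fc = mean(B) − mean(A)`; Benjamini–Hochberg adjustment. A gene with a
zero-variance group reports its fold change but a missing p-value. On null
data the raw-p type-I rate calibrates to 5% (checked at 1000 genes).

## Elementary statistics

`stats_core` implements the tests directly (scipy supplies only distribution
kernels) so their conventions are pinned:

- **Fisher's exact (2×2)**, two-sided by the point-probability criterion:
  sum of hypergeometric probabilities of all same-margin tables whose point
  probability is ≤ the observed one (relative tolerance 1e-7). Clinical
  contingency tables drop `Missing` rows before forming the 2×2; this
  convention reproduces published clinical-table p-values recomputed from
  their printed counts (e.g. 0.014 for an 8,13|130,63 age split and 0.023
  for a 1,1|1,172 nodal split).
- **Wilcoxon rank-sum**: exact enumeration when min(n) ≤ 8 and tie-free,
  else normal approximation with tie and continuity corrections; the two
  paths agree within 0.02 absolute p at 8×8.
- **Correlation**: Pearson, or Spearman on average ranks; p by the
  t-transform with n−2 df (adequate for the cohort sizes in scope, n ≫ 10).
- **BH adjustment**: step-up, capped at 1, original order restored.

## Signature discovery

PCA is an SVD of the centered samples × genes matrix; loadings have
orthonormal columns, scores are `U·S`, components are ordered by variance
and oriented so each component's largest-|loading| gene loads positively.
An independent eigendecomposition of the gene–gene covariance reproduces
the fractions and axes to 1e-6 (tested). Normal samples are excluded from
the fit by default (`include_normals_in_fit=False`); separation is always
scored on the two classes of interest only.

Greedy backward elimination removes, each round, the smallest-|loading| gene
on the refit PC1 whose removal passes two gates:

1. **variance gate** — `VE_1` after ≥ `VE_1` before − ε, ε = 1e-6;
2. **separation gate** — |Welch *t*| of the PC1 scores after ≥ (1 − 0.01) ×
   before.

The variance gate alone cannot stop pruning: for a panel whose informative
genes form an (approximately) equicorrelated block with correlation ρ,
removing any gene raises the PC1 variance *fraction* from λ/p to
(λ−ρ)/(p−1) — an increase whenever ρ ≤ 1 — so a variance-only rule
(`paper_strict=True`) deterministically prunes to `min_size`. A separation
gate on the score AUC (`metric="auc"`) fails differently: under a strong
signature the AUC saturates at exactly 1.0 and removals of genuine signal
genes pass unnoticed until more than half the signature is gone. The |t|
gate with a 1% relative slack is the default because it resolves both
failure modes: removing an uninformative gene perturbs |t| by at most a few
percent in either direction (sampling noise of the refit scores, absorbed
over successive rounds since rejected genes are retried), while removing a
signal carrier from a near-minimal panel costs ≥ ~10%. On the default
synthetic preset this recovers on average 8.7 of 9 planted genes across 10
seeds with ≤ 3 noise genes retained; the 1% value sits on the plateau
between "retains ~20 chance-aligned noise genes" (strict non-decrease) and
"sacrifices planted genes" (≥ 2% slack). Both alternative gates remain
available in `PruneConfig`.

Ties in |loading| (after quantization at 12 decimals, so exact ties are not
split by float round-off) break lexicographically by gene id, which makes
discovery deterministic and equivariant under gene reordering. Candidates
are re-ranked after every accepted removal by default; a ranked-once variant
exists (`rerank_each_step=False`).

## Classification

Logistic fits are maximum likelihood (statsmodels); AIC = 2k − 2·loglik.
Detected complete separation (non-finite or exploding coefficients) falls
back to IRLS with an L2 penalty of 1e-4 on the slopes (intercept
unpenalized) and a warning — with 29-vs-194-scale imbalance and strong
genes, separation is the norm, not the exception. Stepwise selection is
bidirectional from the intercept-only model, applying the single
lowest-AIC move per round while it improves, lexicographic tie-break; the
result never has AIC above the intercept-only model. Note the classical
caveat, which the tests document: AIC admits a spurious candidate with
probability P(χ²₁ > 2) ≈ 0.157, so "exactly the true support" is recovered
in only ~30–50% of runs even at n = 1000 — stepwise-AIC is a ranking
heuristic, not a consistent selector.

ROC curves come from scikit-learn with tie-aware AUC equal to Mann–Whitney
concordance (verified against brute-force pair counting). The decision
threshold maximizes balanced accuracy over all observed scores
(prediction rule: score ≥ threshold), ties toward the smaller threshold.
Training-cohort metrics are resubstitution metrics and flagged as such on
the model object; transfer evaluation applies frozen coefficients and
threshold.

## Survival

Expression is dichotomized at the cohort median, median witnesses to "low"
(an optimal-cutpoint search is deliberately out of scope). KM, log-rank and
Cox estimation are delegated to lifelines; Cox uses Efron tie handling and
reports HR = exp(β) with normal-approximation 95% CIs on the log scale.
The log-rank statistic equals a per-event-time O−E accumulation with
hypergeometric variance (tested exactly on small instances — the same
identity that makes it the Cox score test for a binary covariate).
`cox_backward_select` screens covariates by univariate Wald p < α, then
repeatedly removes the largest-p covariate while it exceeds α (default
0.05), refitting after each removal.

## Enrichment

Genes are ranked by the signal-to-noise metric
`(mean_a − mean_b)/(sd_a + sd_b)` with each sd floored at 0.2·|mean|
(and a 1e-8 absolute floor). The enrichment score is the signed maximum
deviation of a running sum stepping up at hits by |metric|^weight
(normalized over hits) and down at misses by 1/n_miss; weight defaults
to 1; at weight 0 it equals the classical two-sample KS statistic between
hit and miss positions (tested against scipy). Significance comes from
phenotype permutation (default 1000): NES = ES / mean |same-sign
permutation ES|, nominal p = (same-sign permutations at least as extreme
+ 1)/(n_same_sign + 1). Under a null set the mean |NES| calibrates to
~0.9–1.0 (the same-sign conditioning biases it slightly below 1);
a coordinated 0.8-sd shift of a 20-gene set at 30+30 samples is detected
(NES > 1, p < 0.05) in ≥ 8 of 10 seeds. Gene-set collections are read from
standard GMT files; no FDR across collections and no leading-edge analysis.

## Synthetic cohorts

The generator draws class-conditional Gaussians on the log2 scale around a
baseline of 8.0: planted genes shift the metastatic mean by a configured
multiple of the within-class sd (normals sit at the primary mean); blocks
can share a latent factor at a configured correlation; the suppressor-like
gene shares the driver gene's within-class noise at r = −0.6 so inverse
driver–suppressor correlation is testable. The default preset plants 7
up-shifted kinase-like genes plus one down-shifted channel-like and one
down-shifted suppressor-like gene (|shift| = 2 sd) among 78 independent
noise genes, in a 194 primary / 29 metastatic / 29 normal cohort; the
88th gene is the driver itself, excluded from the discovery panel.
Survival times are exponential with hazard `h₀·exp(Σ β_g z_g)`; the
censoring distribution is exponential with its rate solved by bisection so
the expected censored fraction matches the configured rate. Clinical
covariates are independent class-conditional categorical draws.

What a green test does *not* establish: the generator has no batch effects,
no probe-level artifacts, no heavy tails, no gene–gene correlation beyond
the configured blocks, and exponential (not realistic) survival — recovery
results bound behavior under the stated Gaussian world only.

All draws derive from one integer seed through fixed stage-keyed substreams
(expression / DEG / survival / clinical), so regeneration is bit-identical
and toggling one stage never perturbs another's draws.

## Pipeline

`run_full_pipeline` executes simulate → intersect → discover → train →
transfer-evaluate → survival → enrichment, persisting every intermediate as
JSON (sorted keys, no timestamps; the output directory is omitted from the
embedded config echo) so identical configs give byte-identical artifacts.
A stage missing its upstream artifact aborts with the stage name; artifacts
already written are retained.

## Known limitations

- Signature discovery assumes the class signal is concentrated on one
  principal component of the candidate panel; multi-axis signatures would
  be truncated.
- The stepwise-AIC stage inherits AIC's over-selection (see above); treat
  retained borderline genes with skepticism.
- Cox CIs are Wald-type; with < ~30 events they will undercover.
- The 2×2 Fisher path covers dichotomous clinical contrasts only; r×c
  tables are out of scope.
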