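# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Signature scoring

Expression is assumed TPM-like; linear input is transformed to
log2(x + 1) before scoring (generated data is already on the log scale and
is flagged as such). Two single-sample scores are available:

* **mean_z** (default): each gene is z-scored across samples (sample sd,
  ddof = 1; zero-variance genes get z = 0) and a signature scores the mean
  z over its member genes present in the matrix. Member genes absent from
  the matrix are dropped with a log message; a configurable minimum (default
  1 gene) must remain or the signature scores as missing.
* **rank_enrichment**: within each sample, genes get average ranks; the
  score is the mean member rank re-centred and scaled to [−1, 1]. It is
  invariant to any monotone per-sample transform, useful when platforms
  differ.

A single configurable method replaces the heterogeneous per-source scoring
tools used for the original curated signature collections; this trades
per-category fidelity for reproducibility, and only the orientation and
ordering of scores matter downstream (association, ranking), not their
absolute scale.

Scores are standardized per cohort (mean 0, sd 1, ddof = 1) so the logistic
slope is a log-odds ratio per within-cohort SD. Constant rows become zeros
with a warning rather than NaN, so one degenerate cohort cannot poison a
pooled analysis.

## Discovery: per-cohort logistic + random-effects pooling

Per cohort, response (0/1) is regressed on the standardized score with an
intercept + slope logistic model fitted by Newton–Raphson IRLS (tolerance
1e-10, ≤100 iterations). Under complete separation the slope is capped at
|β| = 10, flagged non-converged, and excluded from pooling. Fits need ≥4
samples and both classes.

Cohort slopes are pooled by DerSimonian–Laird with the τ² estimate
truncated at zero and a Wald z-test / CI on the pooled effect (the
classical default of standard meta-analysis software; no Hartung–Knapp
adjustment). With one cohort the pooled effect equals that cohort's and
τ² = 0. Labels: p < 0.05 and OR > 1 → sIGeS; p < 0.05 and OR < 1 → rIGeS;
OR exactly 1 → none (logged). No multiplicity correction is applied to the
labelling rule (a BH column is emitted for reporting only).

**Calibration note.** The truncated-DL + Wald chain is conservative with
few cohorts: with five homogeneous cohorts its exact level at nominal 0.05
is ≈0.037 with known SEs, and ≈0.03 with estimated logistic SEs at 100
samples/cohort. The per-cohort Wald test itself is well calibrated
(≈0.048–0.051 measured). The pipeline therefore over-controls, never
inflates, the type-I rate at desk scale; this is a property of the
estimator, not of the implementation, and is visible in the acceptance
quantities (`null_discovery_label_fraction`).

## Expansion

For each gene x, signature score y and purity z, ranks are taken and the
first-order partial correlation r_xy·z is computed with a t-test on n − 3
df. A constant purity vector degrades gracefully to plain Spearman (n − 2
df, logged). BH FDR is computed per signature across all genes in the
tissue matrix (the adjustment universe is a design choice; the paper-scale
alternative — across a pre-filtered gene list — only makes the filter more
permissive). Filters are strict inequalities: PSCC > 0.4, FDR < 0.05,
DP > 0.8, where DP is the fraction of cell lines with ≥1 read. Survivors
are ranked by PSCC descending (ties by gene id for determinism) and capped
at 200. Original member genes are not force-included; an option unions in
detectable members. An empty expansion falls back to the original members
with DP > 0.8, loudly logged, so the response model never silently loses a
feature.

## Response model

Cohort batch effects are removed by per-cohort location/scale alignment:
each signature is z-scored within a cohort and rescaled to its pooled
mean/sd. This is a deliberate simplification of empirical-Bayes batch
correction: with tens-to-hundreds of samples per cohort and signature-level
(not gene-level) features, the shrinkage that empirical Bayes adds is
marginal, while location/scale alignment removes the dominant additive and
multiplicative batch components.

The classifier is elastic-net logistic regression with nested CV: 5
stratified outer folds; within each outer training set a 10-fold search
over mixing α ∈ {0.1, …, 1.0} and penalty C ∈ {10⁻², …, 10²} (5 log-spaced
values) maximizing inner AUC, implemented with a warm-started
regularization path (saga solver, tolerance 1e-2 — selection is by AUC,
which is insensitive to solver tolerance at this level). Out-of-fold
probabilities are stacked for one overall AUC; the final model is refit on
all samples with hyperparameters selected by inner CV on the full data.
Everything is deterministic given (data, seed). AUC is computed rank-based
(Mann–Whitney, ties half).

Under pure-noise features the stacked out-of-fold AUC is centred at 0.5
with sd ≈ 0.05 per run at 200 samples (hyperparameter selection chasing
noise adds variance beyond the ±0.04 of a random ranking), so calibration
statements should be made on seed-averaged AUCs.

## Compound scoring

* **Ranking.** Metric = treated − control (log scale) per condition;
  descending; exact ties broken by gene id.
* **Prerank GSEA.** Weighted KS running sum with exponent 1 on |metric|;
  ES is the extreme deviation (ties between the positive and negative
  extreme within 1e-12 resolve positive — the convention is also applied by
  the test oracle). The null permutes gene labels (equivalently, member
  positions), 1000 permutations by default, shared across signatures of
  equal size within a condition for speed. NES divides ES by the mean
  |null ES| of matching sign; p is the one-sided permutation tail within
  the matching-sign pool, floored at 1/(pool+1). BH FDR is taken across the
  signatures of each condition. Note the resolution floor: with m
  signatures and nperm permutations the smallest attainable FDR is about
  m/rank × 2/nperm, so nperm must comfortably exceed 2m/0.05 for the
  downstream significance gate.
* **ACAT.** T = Σwᵢ tan((0.5 − pᵢ)π)/Σwᵢ; combined p = 0.5 − arctan(T)/π.
  Valid under arbitrary dependence, appropriate for the correlated
  condition-level FDRs. p at 0/1 is clipped to [1e-15, 1 − 1e-15].
* **PGES.** One reference condition per cell line: exact 10 µM / 24 h, else
  nearest in (log₁₀ dose, log₂ time), ties toward lower dose then shorter
  time. The awarding term f for a cell line is the mean NES difference of
  its non-reference conditions from the reference (the printed formula's
  per-condition quantity is read as the per-condition NES, the only
  per-condition quantity defined; the low/high-dose × short/long-time
  baskets are collapsed into one non-reference pool by default). PGES is
  the mean over cell lines of W_cell · (NES_ref + f); with a single
  condition this reduces exactly to W · NES. W_cell tables are inputs,
  normalized to max 1 per cancer type, with cancer-type-mean then 1.0
  fallbacks.
* **BS.** Sum of Coe_i · PGES_i over signatures with ACAT-combined
  p < 0.05; 0 if none. Compounds are ranked by BS descending within cancer
  type (ties by compound id), percentile = rank/n.
* **Validation statistics.** Known-booster enrichment: effect size = mean
  BS difference, one-sided Wilcoxon rank-sum, "enriched" iff effect > 1 and
  p < 0.05. Cross-source direction consistency: among signatures regulated
  in source A (p.adj < 0.1), the fraction whose NES sign matches in B.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
sizes tuned for sub-minute runs (1000 genes, 40 disjoint 25-gene
signatures, 5 cohorts × 100 samples at 40% responders, 3 cell lines, 60
compounds):

* **Cohorts**: latent activities A_s ~ N(0,1) drive response through a
  logistic model with planted log-ORs and drive member-gene expression
  (unit loading + N(0,1) noise + per-cohort batch shifts of sd 0.5 +
  baseline 5, clipped at 0 on the log scale).
* **Tissue panel**: purity ~ Beta(5,2); signature activities load 0.6 on
  standardized purity, making purity a genuine confounder; target genes
  (3/signature) load on activity with noise sd 0.75 (marginal ρ ≈ 0.8);
  confounder genes load on purity with noise sd 0.5, so their marginal
  score correlation exceeds the 0.4 filter while their partial correlation
  is ≈0. Cell-line counts are Poisson(5) over 10 lines with per-gene
  dropout probabilities to exercise the DP filter.
* **Perturbations**: one vehicle control per (cell line, plate); engineered
  compounds shift the genes of their target signatures by ±magnitude ×
  a dose/time scale (monotone in log-dose, 1 at the 10 µM/24 h reference);
  null compounds shift random non-signature genes; treated profiles add
  N(0, 0.25) noise. Defaults engineer one booster (up all sIGeS, down all
  rIGeS) and its inversion.

All generators are pure functions of the spec (which embeds the seed).

What the generator does **not** emulate: count-distribution effects
(expression is Gaussian on the log scale — downstream statistics are rank-
or z-based), gene–gene correlation beyond shared signature membership,
signature overlap, platform differences, single-cell structure, dose–
response saturation, or the L1000 landmark-imputation error of real
perturbation data. Passing tests therefore demonstrate correctness of the
statistical machinery and its calibration under the assumed model, not
performance on real cohorts.

## Numerical conventions and degenerate inputs

Sample sds use ddof = 1 throughout. Constant score rows standardize to
zero with a warning. Logistic separation caps |β| at 10 and excludes the
cohort from pooling. Permutation p-values are floored at 1/(nperm+1)-scale
and never 0; ACAT clips at 1e-15. All orderings that could tie (gene rank
metric, PSCC at the cap boundary, BS ranking) break ties lexicographically
so outputs are byte-identical across reruns with one seed; TSV writers use
a fixed float format for the same reason.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run discovery calibration on
1000 null signatures (25 replicates of the default universe), power and
recovery at the default 5 × 100 cohort design (20 and 200 replicates),
expansion on a 500-gene/200-sample panel, elastic-net checks at 40
features × 200 samples, and end-to-end compound ranking on the default 60-
compound universe; these sizes were chosen as the smallest at which the
binomial/simulation error bars are informative for the properties being
checked.

## Known limitations

* The truncated-DL pooled test is conservative for small numbers of
  cohorts (see calibration note); consumers needing exact level control at
  k ≤ 10 should interpret the p = 0.05 gate as conservative.
* The unified scoring method is a stand-in for the per-source scoring tools
  of the original curated collections, not a claim of equivalence.
* Empirical-Bayes batch correction is approximated by location/scale
  alignment.
* The expansion's FDR universe and the "top 200 by PSCC" ordering are
  documented choices where the method description is ambiguous
  (alternatives: |PSCC| or FDR ordering).
* PGES aggregation interprets the awarding function's per-condition
  quantity as the per-condition NES and pools all non-reference conditions
  of a cell line (basket structure collapsed).
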