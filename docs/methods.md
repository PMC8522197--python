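# Methods

## The model

`lncpair` implements a prognostic signature built from *relative orderings*
of long non-coding RNA (lncRNA) expression rather than from expression
levels. For an ordered gene pair (B, C) and sample *s* the feature is the
binary indicator

    A(B,C,s) = 1  if  expr(B,s) > expr(C,s),  else 0   (ties count as 0)

Because the indicator only compares two genes *within* the same sample, the
whole signature is invariant to any strictly increasing per-sample transform
of the expression profile — sequencing depth, FPKM-vs-TPM unit choices and
most normalisation differences cancel out. This is the same idea as
top-scoring-pair classifiers, applied to survival.

The per-sample risk score is the Cox linear predictor over the selected
pairs, `score(s) = Σ_i β_i · A_i(s)`, and patients are dichotomised into
high/low risk at a cutoff chosen by AIC (below).

## Candidate gene screening

1. **Biotype partition.** A GTF annotation splits the matrix into lncRNAs
   (configurable biotype set, default Ensembl's
   lncRNA/lincRNA/antisense/processed_transcript/sense_intronic/
   sense_overlapping) and protein-coding mRNAs; other biotypes are dropped
   with a logged count.
2. **Immune-relatedness.** A lncRNA is *immune-related* if it correlates
   with at least one gene of a curated immune list (an ImmPort-style set)
   with |r| > 0.5 (strict) and P < 0.05. Pearson on log2(FPKM + 1) is the
   default; Spearman and raw-scale values are config options. We compute the
   correlation on the log scale because FPKM-scale Pearson is dominated by
   the few heaviest samples; the threshold semantics are unchanged. The
   correlation uses tumor and normal samples jointly (tumor-only is an
   option; the choice is not critical at the default effect sizes).
3. **Differential expression.** Welch's two-sample t-test on log2(x + 1)
   per gene, tumor vs normal, with Benjamini–Hochberg correction across all
   tested genes; a gene passes with |log2FC| > 2 and FDR < 0.05. The
   log-fold-change threshold is configurable because "fold change > 2" is
   ambiguous between FC > 2 (|log2FC| > 1) and |log2FC| > 2; the stricter
   reading is the default. A moderated-variance test would differ only for
   very small groups; plain Welch keeps the statistic transparent and
   oracle-checkable.

The DE-ir-lncRNA set is the intersection of the two pass sets.

## Pair construction and filtering

All k·(k−1)/2 unordered pairs of DE-ir-lncRNAs are formed, stored in
canonical orientation (lexicographically smaller gene first). Pairs are
built on **tumor samples only** — the model is prognostic and normal
samples have no survival data; normals contribute only to the DE screen.
A pair whose indicator frequency f (row mean) satisfies f ≤ 0.2 or f ≥ 0.8
is removed: a near-constant indicator carries no prognostic contrast. The
upper bound mirrors the lower one because the frequency of the flipped
orientation is 1 − f; both bounds are configurable and strict.

## Pair selection

1. **Univariate Cox screen** (Wald P < 0.05 per pair). Single-covariate
   Cox fits on a 0/1 covariate reduce, at each distinct event time, to
   event and at-risk counts split by the indicator, so a dedicated Newton
   solver on the Breslow partial likelihood vectorises over thousands of
   pairs at once (`lncpair._cox`). Monotone likelihoods (perfect
   separation) are detected, the coefficient capped at |β| = 15 and the
   pair flagged rather than crashed.
2. **Repeated lasso-Cox.** Each cycle draws 80% of the samples without
   replacement (cycle-specific RNG stream derived from the master seed, so
   any cycle is reproducible in isolation), fits an L1-penalised Cox
   coefficient path (glmnet-style, via scikit-survival), and picks the
   penalty minimising the 5-fold cross-validated held-out partial-likelihood
   deviance (minimum rule, not 1-SE — deliberately inclusive, the
   count threshold does the pruning). Pairs with a nonzero coefficient are
   counted; pairs selected in more than `count_threshold` of `n_cycles`
   cycles go forward. Defaults are 1000 cycles / threshold 100; reduced
   runs keep the 10% ratio (e.g. 50/5). Cycles that fail to converge are
   redrawn up to 3 times; an overall failure rate above 10% aborts.
3. **Forward AUC scan.** Candidates are ranked by selection count (pair id
   as the deterministic tie-break) and added one at a time to a nested
   multivariate Cox model (lifelines). Each nested model's linear predictor
   is scored by the IPCW time-dependent AUC at the evaluation horizon
   (default 1 year); the chosen size is the *first* index attaining the
   maximal AUC. Note the in-sample AUC of a refit richer model is generically
   non-decreasing, so the scan tends to keep weak extra pairs when their
   marginal AUC gain is positive; the lasso count threshold is what keeps
   the candidate list short.
4. **AIC-optimal cutoff.** Candidate cutoffs are midpoints between
   consecutive distinct scores, restricted so each group keeps ≥ 10% of
   samples. For each candidate a single-covariate Cox model on the binary
   split {score > c} is fitted and AIC = 2 − 2·log PL evaluated; the
   smallest minimising cutoff wins.

## Validation and downstream association

* **Kaplan–Meier / log-rank** per risk group (lifelines).
* **Time-dependent ROC** at 1/3/5 years: cumulative-case / dynamic-control
  (Uno-type) estimator with inverse-probability-of-censoring weights
  1/G(Tᵢ⁻) from the censoring Kaplan–Meier curve; implemented directly so
  the full ROC curve is available, and cross-checked in the tests against
  scikit-survival's `cumulative_dynamic_auc`. Ties in the score count 1/2,
  making the no-censoring case exactly a Mann–Whitney statistic.
* **Clinical associations**: categorical covariates by chi-squared on the
  risk-group contingency table, switching to two-sided Fisher's exact for
  sparse 2×2 tables (expected cell < 5 or an observed zero); continuous
  covariates (age) by Wilcoxon rank-sum between risk groups.
* **Clinical Cox models**: univariate and multivariate with stage (I–IV →
  1–4) and grade (low/high → 0/1) ordinal-encoded and the risk score
  continuous; Wald 95% CIs.
* **Immune / drug panels**: infiltration and predicted-IC50 matrices are
  *inputs* (their provenance recorded in `source_label`); per feature we
  report the rank-sum test between risk groups with a median-based
  direction, and the Spearman correlation with the continuous score.
  Although high/low risk groups are independent samples, the group
  comparison is often loosely called a "Wilcoxon signed-rank" in the
  applied literature; the correct independent-samples rank-sum
  (Mann–Whitney) test is what runs. A raw P < 0.05 flag matches common
  practice; a BH-adjusted column is emitted alongside. For drug panels,
  lower IC50 means more sensitive, so direction `higher_in_low_risk` reads
  "high-risk patients predicted more sensitive".

## The synthetic cohort generator

The generator (`lncpair.simulate`) emulates a TCGA-like bulk RNA-seq cohort
with every structure the pipeline assumes, at a reduced default scale
(60 tumor + 15 normal samples; 300 mRNAs of which 50 immune; 150 lncRNAs)
chosen to keep a full run in seconds while leaving every screen
non-trivially powered:

* expression is log-normal: log2 values Gaussian per gene (spread 1.0),
  exponentiated to an FPKM-like scale;
* 40 lncRNAs load on a parent immune mRNA (slope 1.3 on the log2 scale,
  residual SD 0.5), so their correlation clears the r > 0.5 screen with
  high probability on the screen's working scale;
* 20 lncRNAs get a ±3.0 log2 tumor shift (80% up), large enough that the
  DE filter's power is ≈ 1 at default sample sizes;
* 3 prognostic pairs are formed from consecutive DE, immune-linked
  lncRNAs; members of a pair share a parent and a mean, so the indicator is
  a balanced coin per sample. Survival follows a proportional-hazards model
  with Weibull baseline (shape 1 = exponential, rate 0.10/year) and linear
  predictor Σ βₖ·Aₖ with planted β = (1.0, 1.25, 1.5); censoring is an
  independent exponential (0.08/year) truncated at 10 years of follow-up.
  The indicators entering the hazard are recomputed from the *emitted*
  expression matrix, so generator and pipeline see exactly the same
  features;
* infiltration (12 cell types, 4 shifted) and drug-IC50 (8 drugs, 4
  shifted, half in each direction) panels are Gaussian score matrices with
  a 1.5 SD mean shift between samples above/below the median true linear
  predictor; four checkpoint-style genes (DDR2, HAVCR2, LAG3, CTLA4) are
  added to the mRNA compartment with the first two shifted;
* which genes are DE/immune-linked and which pairs are prognostic is a
  deterministic function of the configuration; the seed drives only the
  random draws. Two cohorts with the same configuration and different
  seeds therefore share their planted pairs, which makes held-out
  validation of a recovered model meaningful.

What the generator does **not** emulate: read-level count noise (negative
binomial), batch effects, molecular subtypes, correlated clinical
covariates, or informative censoring. Passing tests therefore demonstrate
the pipeline's statistical correctness and its behaviour at planted effect
sizes — not performance on real tumor transcriptomes.

## Numerical choices and degenerate inputs

* Cox tie handling: the vectorised univariate solver uses Breslow; the
  multivariate fits (lifelines) use Efron. On tie-free survival times the
  two coincide exactly, and the generator produces continuous times.
* Newton steps are damped to |Δβ| ≤ 2 and coefficients capped at |β| = 15
  (separation flag). Zero-variance covariates are rejected by name.
* Zero-variance genes in the correlation screen are reported failed with a
  reason; a gene constant in both DE groups with equal means gets p = 1.
* Risk-score ties: `group = high` iff score **strictly** exceeds the
  cutoff; AIC ties resolve to the smaller cutoff; AUC ties in the forward
  scan resolve to the smaller model.
* All RNG streams derive from one master seed (`numpy` SeedSequence
  spawning by `[seed, cycle, retry]`), so results are independent of
  execution order.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the default-scale cohort for
the end-to-end path, 50 lasso cycles with threshold 5 (the same 10%
retention ratio as the 1000/100 defaults), 50 null-cohort seeds for type-I
calibration, and 25 seeds of a 200-tumor cohort (three planted pairs,
log hazard ratios 1.0–1.5, censoring_rate 0.22 giving ≈ 30% censoring) for
parameter recovery with a held-out cohort per seed. These sizes are the
package's own choice of a desk-scale experiment; all of them are plain
configuration and scale up freely.
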