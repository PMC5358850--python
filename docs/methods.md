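# Methods

## Scope and data model

`qpcrsig` analyses duplicate-well qRT-PCR validation studies of
gene-expression signatures. The inputs are a long-format replicate-level Ct
table (sample, gene, replicate, plate, Ct or an "Undetermined" token), a
clinical annotation mapping samples to lymph-node status (LN+/LN−) plus
optional covariates, and a signature definition (gene list, per-gene
direction of regulation in LN+ disease, housekeeping genes, ΔCt reference
genes, Ct ceiling). An optional genes × samples expression matrix with
group labels supports an external-cohort comparison. The shipped default
signature is the 20-gene lymph-node-metastasis panel; only eight direction
labels are documented for it (AVL9, PCMTD2, FAM36A/COX20, LIMCH1, RAB15 up
in LN+; NCLN, MAP4K4, MMP14 down), and the remaining twelve are left
unspecified rather than guessed — they must be supplied before scoring.
The synthetic module fixes its own full 20-direction convention so
simulated cohorts can score every gene; that assignment is a synthetic
convention, not biology.

## Quality control

QC annotates, it never deletes: every input measurement survives with a
status flag, and discard decisions are recorded per sample.

1. **Replicate reconciliation.** Within each (sample, gene) duplicate, an
   undetermined well inherits the determined partner's Ct
   (`imputed_from_replicate`); if all wells are undetermined both are set
   to the Ct ceiling, default 35 cycles (`ceiling_undetermined`). The
   ceiling is the instrument's effective censoring limit, so such values
   are treated as data (retained in ΔCt by default; `ceiling_policy=
   "missing"` drops them instead).
2. **Reliability interval.** Per transcript, readings outside
   mean ± 1.96 SD (sample SD over all non-ceiling readings of that gene
   across samples) become `unreliable`. Ceiling values neither enter the
   interval (they are artificial and would drag it) nor get re-flagged.
   The multiplier is configurable; genes with fewer than three usable
   readings are skipped with a warning. In the SD = 0 limit equal values
   pass and any deviation flags. The interval can also be learned on one
   cohort and applied to another via the `CtQualityControl` transformer.
3. **Sample discard.** A sample is discarded when its housekeeping genes
   (ACTB + HPRT, replicate-level, pooled) accumulate two or more
   ceiling-undetermined or unreliable data points, or lack a housekeeping
   gene entirely.

The interval is computed cohort-wide on reconciled replicate-level values.
Plate-wise alternatives exist in the literature but need more samples per
plate than a two-patient plate design provides.

## Normalization and scoring

Usable replicates (unreliable excluded under the default `collapse="mean"`;
`"keep-all"` retains them for sensitivity probes) are averaged per
(sample, gene), and the per-sample mean reference Ct — ACTB alone by
default, as the highest-expressed and least-missing housekeeping gene — is
subtracted: ΔCt = collapsed Ct − mean reference Ct. Cells with no usable
replicate are missing. ΔCt is computed on collapsed per-patient values; all
downstream statistics are per patient.

The risk score is `mean(ΔCt of down-in-LN+ genes) − mean(ΔCt of up-in-LN+
genes)`. Missing genes drop out of their direction mean (at least
`min_genes` = 1 per direction required, `strict` demands the full panel);
no imputation, no sign flip, and no classification threshold — the score is
evaluated as a continuous marker by ROC only.

## Statistics

- **ROC/AUC** with midrank half-credit for ties; the curve comes from
  scikit-learn and the AUC equals the trapezoidal area and the scaled
  Mann–Whitney U. Confidence intervals: DeLong by default (hand-written
  midrank implementation, cross-checked against R's pROC in the test
  suite), or a seeded stratified percentile bootstrap (2000 draws).
  Constant scores give AUC 0.5 with a flagged degenerate CI.
- **Per-gene logistic odds ratios** per ΔCt cycle (statsmodels maximum
  likelihood, Wald 95% CI). Complete separation yields a flagged row with
  infinite CI; constant predictors an error row. The multivariate model
  reports the in-sample linear-predictor AUC (no cross-validation,
  matching the original analysis).
- **Mann–Whitney U**, two-sided, U reported for the first group; exact
  null distribution when n₁·n₂ ≤ 400 and untied, tie-corrected normal
  approximation otherwise.
- **Correlation clustering**: pairwise-complete Pearson r, complete
  linkage on d = 1 − r, cluster labels at a configurable cut height
  (default d = 0.34, i.e. r ≥ 0.66, the reported within-cluster range).
  Constant genes are excluded with a warning.
- **Cohort tables**: categorical covariates get per-group counts and
  percentages over the full group including an explicit Unknown level
  (rounded half away from zero, as clinical tables do), with Fisher's
  exact test (2×2) or chi-square (larger) on the known levels only;
  continuous covariates get mean/range and Mann–Whitney. No
  multiple-testing correction anywhere, matching the original analysis.
- Samples without LN status are QC'd and normalized but excluded from all
  statistics; attrition satisfies input = analyzed + discarded +
  annotation-missing.

## Synthetic cohorts

The generator emulates the validation study's design: 91 LN− and 48 LN+
patients, duplicate wells, two patients per plate (randomly paired),
housekeeping ACTB (baseline Ct 20) and HPRT (24) with zero group effect.
Per patient and gene, the latent Ct is baseline + ΔΔCt·[LN+] + biological
noise (SD 1.0 cycle); each replicate adds technical noise (SD 0.25) and
drops out to "Undetermined" with probability `logistic((Ct − 34)/1.5)`.
Noise and dropout magnitudes are engineering choices — the source study
reported duplicates as robust without numbers — picked so the QC rules
fire at realistic rates (a few percent imputation and unreliability, ~5%
sample discard). Randomness is split per gene from one seed via
counter-based substreams, so adding genes never perturbs other genes'
draws. Effects are specified as ΔΔCt in LN+; `direction_consistent_effects`
assigns −m to up-regulated and +m to down-regulated genes so the score
rises in LN+.

The closed-form oracle `expected_auc` treats the score as Gaussian: the
reference-gene term cancels exactly in the down-minus-up score, giving
mean shift Δμ = mean(down effects) − mean(up effects) and per-group
variance v·(1/n_down + 1/n_up) with v = biological_sd² + replicate_sd²/R;
AUC = Φ(Δμ/(σ√2)). The oracle ignores dropout/ceiling censoring and the
reliability truncation (see limitations).

The expression-cohort generator draws log-normal values per gene with a
log-scale group shift, 365 samples by default (237/128 split), mirroring
the external RNA-seq comparison cohort's size.

## What passing tests show — and what they do not

The synthetic cohorts are Gaussian on the Ct scale with independent genes,
no plate/batch effects, no pre-amplification bias and no RNA-quality
covariates. Calibration results (null AUC ≈ 0.5, DeLong coverage ≈ 95%,
effect recovery against the oracle) therefore validate the pipeline's
arithmetic and its statistical calibration, not the behaviour of the assay
on real FFPE material, where correlated genes and site effects are the
interesting failure modes.

Problem sizes used by the shipped calibration suites: 500 null cohorts and
100 cohorts per effect size at the full 91 + 48 design; 1000 random
instances for the AUC/pair-counting identity; exhaustive enumeration up to
group sizes 5 for the exact Mann–Whitney oracle; 200 replicates of
n = 2000 for logistic odds-ratio recovery.

## Known limitations

- **Reliability truncation bias.** The mean ± 1.96 SD rule flags ~5% of
  perfectly clean Gaussian readings, preferentially each group's
  informative tail. Excluding them (the default, matching the source
  procedure where flagged data are set unreliable) shrinks group
  separation: at a ΔΔCt effect of 0.5 cycles the pipeline's mean AUC is
  ≈ 0.027 below the closed-form oracle (≈ 0.005 with `collapse=
  "keep-all"`). The oracle deliberately does not model this truncation;
  the discrepancy is a property of the QC rule, documented rather than
  hidden. At null and at larger effects the gap is negligible.
- The ceiling pins fully-undetermined pairs at 35 regardless of shifts,
  so Ct-level shift invariance holds exactly only for measured values.
- Per-sample shift invariance of ΔCt holds for the arithmetic; the
  cohort-relative reliability rule may legitimately re-flag a shifted
  sample.
- DeLong CIs are Wald-type on the probability scale, clipped to [0, 1];
  for AUC near the boundaries a logit-scale or bootstrap interval may
  behave better.
- No amplification-efficiency correction, standard-curve modelling, or
  inter-plate calibration: the comparative ΔCt method assumes efficiency
  near 1.
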