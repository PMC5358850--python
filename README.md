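# qpcrsig

Quality control, ΔCt normalization and validation statistics for
qRT-PCR gene-expression signatures, built around the 20-gene
lymph-node-metastasis panel for muscle-invasive bladder cancer.

## The problem

Deciding whether a bladder-cancer patient should receive neoadjuvant
chemotherapy before radical cystectomy hinges on predicting occult lymph-node
metastasis from the diagnostic tumor resection. One proposed tool is a
20-gene expression signature assayed by qRT-PCR on FFPE-derived RNA.
Validating such a signature on duplicate-well plate data requires a chain of
small but consequential analysis decisions — how to reconcile undetermined
wells, when a Ct reading is unreliable, when a sample must be discarded, how
to normalize and score — followed by the discrimination statistics that
decide whether the signature works. `qpcrsig` implements that chain as a
reusable, tested pipeline, plus a synthetic plate-data generator so every
stage can be exercised and calibrated without patient data.

## The method

For each sample *i* and gene *g*, duplicate Ct readings are reconciled
(an undetermined well inherits its partner's Ct; fully undetermined pairs
are set to the ceiling Ct = 35), readings outside the per-transcript 95%
interval (mean ± 1.96 SD) are flagged unreliable, and samples with ≥ 2
flagged housekeeping data points (ACTB + HPRT) are discarded. Normalized
expression is

    ΔCt(i, g) = Ct(i, g) − mean Ct(i, ACTB)

and the per-sample risk score is

    score(i) = mean{ΔCt(i, g) : g down-regulated in LN+} −
               mean{ΔCt(i, g) : g up-regulated in LN+}

so higher scores match the node-positive expression pattern. Validation
statistics: per-gene logistic odds ratios per ΔCt cycle with Wald 95% CIs,
ROC/AUC of the risk score with DeLong (or seeded-bootstrap) confidence
intervals, Pearson gene–gene correlation with complete-linkage clustering on
1 − r distances, Mann–Whitney per-gene tests for an external expression
cohort, and Fisher/chi-square/Mann–Whitney cohort-table comparisons.

The QC → normalization → scoring stages are also exposed as
scikit-learn-compatible transformers (`CtQualityControl`, `DeltaCtNormalizer`,
`SignatureScorer`) that compose with `sklearn.pipeline`.

## Worked example

Simulate a cohort at the validation study's size (91 node-negative, 48
node-positive patients, two replicates, two patients per plate) with a
direction-consistent ΔΔCt effect of 0.5 cycles, then run the full pipeline:

```python
from qpcrsig import (SimulationConfig, RunConfig, run_validation,
                     simulate_ct_cohort, synthetic_signature,
                     direction_consistent_effects)

sig = synthetic_signature()
cfg = SimulationConfig(seed=7, signature=sig,
                       effect=direction_consistent_effects(sig, 0.5))
table, ann, truth = simulate_ct_cohort(cfg)
report = run_validation(RunConfig(ct_table=table, annotation=ann,
                                  signature=sig, seed=7,
                                  multivariate_genes=("BST2", "IFI27")))
```

Summarising `report` (QC summary, ROC result, top odds-ratio rows) prints:

```
samples: 139 input, 11 discarded, 128 analyzed
flag counts: {'ok': 5688, 'imputed_from_replicate': 115,
              'ceiling_undetermined': 2, 'unreliable': 311}
risk-score AUC: 0.933 (95% CI 0.889-0.976), 43 LN+ vs 85 LN-
closed-form oracle AUC for this configuration: 0.940
  MAP4K4: OR 1.89 (1.30-2.76), p=0.001
  NCLN: OR 1.63 (1.21-2.20), p=0.001
bivariate BST2+IFI27 AUC: 0.614 (0.498-0.730)
```

Eleven samples fell to the housekeeping discard rule, the risk score
recovers the simulated separation (empirical AUC 0.933 against the
closed-form 0.940 implied by the noise model), and per-gene odds ratios are
largest for genes that carry the planted effect. With `effect=0` the same
pipeline gives AUC ≈ 0.5, the behaviour a negative validation would show.

The same steps are available as a CLI:

```sh
qpcrsig simulate --n-neg 91 --n-pos 48 --effect 0.5 --seed 7 --outdir sim/
qpcrsig qc sim/ct_table.csv --outdir qc/
qpcrsig normalize sim/ct_table.csv --out dct.csv
qpcrsig score dct.csv --signature sim/signature.yaml --out scores.csv
qpcrsig evaluate sim/ct_table.csv sim/annotation.csv --outdir results/
```

## Layout

- `src/qpcrsig/io.py` — Ct tables, annotations, signature configs, matrices
- `src/qpcrsig/qc.py` — replicate reconciliation, reliability flagging,
  sample discard, ΔCt normalization (+ sklearn transformers)
- `src/qpcrsig/score.py` — signature risk score
- `src/qpcrsig/stats.py` — ROC/AUC + DeLong, logistic ORs, Mann–Whitney,
  correlation clustering, cohort tables
- `src/qpcrsig/simulate.py` — synthetic plate and expression cohorts,
  closed-form AUC oracle
- `src/qpcrsig/pipeline.py`, `src/qpcrsig/cli.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
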