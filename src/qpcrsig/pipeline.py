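"""End-to-end orchestration: read -> QC -> dCt -> score -> statistics,
with a written report and an attrition-consistent QC summary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .model import (
    NEGATIVE,
    POSITIVE,
    DeltaCtResult,
    QcTable,
    SignatureDefinition,
)
from .qc import compute_delta_ct, run_qc
from .score import compute_risk_score
from .stats import (
    CohortRow,
    CorrelationResult,
    RocResult,
    cohort_table,
    correlation_cluster,
    expression_test_table,
    group_means,
    multivariate_model,
    or_table,
    roc_auc,
)


@dataclass
class RunConfig:
    """Everything a validation run needs; paths or in-memory tables."""

    ct_table: str | pd.DataFrame
    annotation: str | pd.DataFrame
    signature: str | SignatureDefinition
    expression_matrix: str | pd.DataFrame | None = None
    expression_groups: str | pd.Series | None = None
    interval_multiplier: float = 1.96
    collapse: str = "mean"
    ceiling_policy: str = "retain"
    min_genes: int = 1
    ci_method: str = "delong"
    n_boot: int = 2000
    seed: int = 0
    multivariate_genes: tuple[str, ...] | None = None
    covariates: tuple[str, ...] | None = None
    cluster_cut_height: float = 0.34
    outdir: str | None = None


@dataclass
class EvaluationReport:
    """All numeric outputs of one validation run."""

    qc_summary: dict
    qc: QcTable
    delta_ct: DeltaCtResult
    risk_scores: pd.DataFrame
    roc: RocResult
    or_table: pd.DataFrame
    correlation: CorrelationResult
    gene_group_means: pd.DataFrame
    cohort_rows: list[CohortRow] = field(default_factory=list)
    multivariate: tuple[RocResult, pd.DataFrame] | None = None
    external_tests: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def _load(cfg: RunConfig):
    ct = cfg.ct_table if isinstance(cfg.ct_table, pd.DataFrame) \
        else qio.read_ct_table(cfg.ct_table)
    ann = cfg.annotation if isinstance(cfg.annotation, pd.DataFrame) \
        else qio.read_annotation(cfg.annotation)
    sig = cfg.signature if isinstance(cfg.signature, SignatureDefinition) \
        else qio.read_signature_config(cfg.signature)
    expr = grp = None
    if cfg.expression_matrix is not None:
        if isinstance(cfg.expression_matrix, pd.DataFrame):
            expr, grp = cfg.expression_matrix, pd.Series(cfg.expression_groups)
        else:
            expr, grp = qio.read_expression_matrix(
                cfg.expression_matrix, cfg.expression_groups
            )
    return ct, ann, sig, expr, grp


def run_validation(cfg: RunConfig) -> EvaluationReport:
    """Execute the full validation and optionally write the report.

    Samples lacking an LN status are QC'd and normalized but excluded from
    every statistic; the QC summary's attrition counts satisfy
    ``input = analyzed + discarded + annotation_missing``.
    """
    ct, ann, sig, expr, grp = _load(cfg)
    if cfg.seed is not None and cfg.seed >= 2 ** 31:
        raise ValueError("seed must fit in 31 bits")

    qc = run_qc(ct, sig, interval_multiplier=cfg.interval_multiplier)
    dct = compute_delta_ct(qc, sig, collapse=cfg.collapse,
                           ceiling_policy=cfg.ceiling_policy)
    scores = compute_risk_score(dct, sig, min_genes=cfg.min_genes)

    status = ann.set_index("sample_id")["ln_status"]
    if sig.plate_control is not None:
        scores = scores.drop(index=sig.plate_control, errors="ignore")
    labeled = scores.join(status).dropna(subset=["ln_status"])
    labeled = labeled[labeled["ln_status"].isin((POSITIVE, NEGATIVE))]

    input_samples = sorted(set(ct["sample_id"]))
    discarded = set(qc.discarded_samples)
    with_label = set(labeled.index)
    ann_missing = [s for s in input_samples
                   if s not in discarded and s not in with_label]
    qc_summary = {
        "n_input_samples": len(input_samples),
        "n_discarded": len(discarded),
        "n_annotation_missing": len(ann_missing),
        "n_analyzed": len(with_label),
        "flag_counts": qc.flag_counts().to_dict(),
        "discard_reasons": dict(zip(qc.discards["sample_id"],
                                    qc.discards["reason"])),
    }

    usable = labeled.dropna(subset=["risk_score"])
    roc = roc_auc(usable["risk_score"], usable["ln_status"],
                  ci_method=cfg.ci_method, n_boot=cfg.n_boot, seed=cfg.seed)
    dct_labeled = dct.matrix.loc[dct.matrix.index.isin(with_label)]
    ors = or_table(dct_labeled, ann)
    corr = correlation_cluster(dct_labeled, cut_height=cfg.cluster_cut_height)
    means = group_means(dct_labeled, ann)

    covs = cfg.covariates
    if covs is None:
        covs = tuple(c for c in ann.columns if c not in ("sample_id", "ln_status"))
    ann_analyzed = ann[ann["sample_id"].isin(with_label)]
    rows = cohort_table(ann_analyzed, covs) if covs else []

    multi = None
    if cfg.multivariate_genes:
        multi = multivariate_model(dct_labeled, ann, list(cfg.multivariate_genes))

    external = None
    if expr is not None:
        sig_genes = [sig.resolve(g) if sig.resolve(g) in expr.index else g
                     for g in sig.genes]
        present = [g for g in sig_genes if g in expr.index]
        external = expression_test_table(expr, grp, POSITIVE, NEGATIVE,
                                         genes=present)

    report = EvaluationReport(
        qc_summary=qc_summary, qc=qc, delta_ct=dct, risk_scores=labeled,
        roc=roc, or_table=ors, correlation=corr, gene_group_means=means,
        cohort_rows=rows, multivariate=multi, external_tests=external,
        params={f.name: _param_repr(getattr(cfg, f.name))
                for f in dataclasses.fields(cfg)},
    )
    if cfg.outdir is not None:
        write_report(report, cfg.outdir)
    return report


def _param_repr(v):
    if isinstance(v, (pd.DataFrame, pd.Series)):
        return f"<in-memory {type(v).__name__}>"
    if isinstance(v, SignatureDefinition):
        return "<in-memory SignatureDefinition>"
    return v


def write_report(report: EvaluationReport, outdir) -> list[Path]:
    """Write all report tables as CSV plus a JSON summary.

    Output is deterministic: identical reports produce byte-identical
    files (stable column order, sorted JSON keys).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str, index: bool):
        p = outdir / name
        df.to_csv(p, index=index)
        written.append(p)

    _csv(report.risk_scores, "risk_scores.csv", index=True)
    _csv(report.or_table[["gene", "odds_ratio", "ci_low", "ci_high",
                          "p_value", "n_used", "note"]],
         "or_table.csv", index=False)
    _csv(pd.DataFrame({"fpr": report.roc.fpr, "tpr": report.roc.tpr,
                       "threshold": report.roc.thresholds}),
         "roc_curve.csv", index=False)
    _csv(report.correlation.corr, "correlation_matrix.csv", index=True)
    _csv(report.correlation.clusters.rename_axis("gene").to_frame(),
         "cluster_memberships.csv", index=True)
    _csv(report.gene_group_means, "gene_group_means.csv", index=True)
    _csv(report.qc.discards, "qc_discards.csv", index=False)
    _csv(report.delta_ct.matrix, "delta_ct_matrix.csv", index=True)
    if report.cohort_rows:
        frames = []
        for row in report.cohort_rows:
            t = row.table.copy()
            t.insert(0, "covariate", row.covariate)
            t.insert(1, "level", t.index.astype(str))
            t["test"] = row.test_name
            t["p_value"] = row.p_value
            frames.append(t.reset_index(drop=True))
        _csv(pd.concat(frames, ignore_index=True), "cohort_table.csv", index=False)
    if report.multivariate is not None:
        _csv(report.multivariate[1], "multivariate_coefficients.csv", index=False)
    if report.external_tests is not None:
        _csv(report.external_tests, "external_cohort_tests.csv", index=False)

    summary = {
        "qc_summary": report.qc_summary,
        "roc": report.roc.as_dict(),
        "multivariate_auc": (report.multivariate[0].as_dict()
                             if report.multivariate else None),
        "cluster_cut_height": report.correlation.cut_height,
        "params": report.params,
    }
    p = outdir / "summary.json"
    qio.write_json(summary, p)
    written.append(p)
    return written
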