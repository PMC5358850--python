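"""Ct-level quality control and delta-Ct normalization.

The QC procedure mirrors standard practice for duplicate-well qRT-PCR data:

1. **Replicate reconciliation** — if one well of a duplicate is undetermined
   it inherits the determined well's Ct (flag ``imputed_from_replicate``);
   if both are undetermined both are set to the Ct ceiling (default 35,
   flag ``ceiling_undetermined``).
2. **Reliability gating** — within each transcript, readings outside the
   central 95% interval (mean +/- 1.96 SD over all non-ceiling readings)
   are flagged ``unreliable``. Ceiling values never enter the interval and
   are never re-flagged.
3. **Sample discard** — a sample is dropped when its housekeeping genes
   (ACTB + HPRT) accumulate two or more undetermined-or-unreliable
   replicate-level data points, or lack a housekeeping gene entirely.
4. **Normalization** — per (sample, gene) the usable replicates are
   collapsed (mean, excluding unreliable readings by default) and the
   per-sample mean reference-gene Ct (ACTB) is subtracted, giving dCt.

No QC step drops measurements: flags and discard decisions annotate the
table, and discarded samples are excluded only when the dCt matrix is built.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import (
    CEILING_UNDETERMINED,
    IMPUTED_FROM_REPLICATE,
    OK,
    UNRELIABLE,
    DeltaCtResult,
    QcTable,
    SignatureDefinition,
)


class QcError(ValueError):
    pass


def reconcile_replicates(
    table: pd.DataFrame, sig: SignatureDefinition, strict: bool = True
) -> QcTable:
    """Resolve undetermined readings within each (sample, gene) replicate set.

    Undetermined readings with at least one determined partner copy the
    partner Ct (mean of determined partners when more than one) and are
    flagged ``imputed_from_replicate``; fully undetermined sets are assigned
    the Ct ceiling and flagged ``ceiling_undetermined``.
    """
    df = table.copy()
    if "undetermined" not in df.columns:
        df["undetermined"] = df["ct"].isna()
    if "status" not in df.columns:
        df["status"] = OK

    grp = df.groupby(["sample_id", "gene"], sort=False)
    n_rep = grp["undetermined"].transform("size")
    if strict and (n_rep > 2).any():
        key = df.loc[n_rep > 2, ["sample_id", "gene"]].iloc[0].tolist()
        raise QcError(f">2 replicates for {key} (strict mode)")
    n_und = grp["undetermined"].transform("sum")
    det_mean = df["ct"].groupby([df["sample_id"], df["gene"]], sort=False).transform("mean")

    und = df["undetermined"].to_numpy(bool)
    all_und = und & (n_und == n_rep).to_numpy()
    some_det = und & ~all_und
    ct = df["ct"].to_numpy(float).copy()
    ct[some_det] = det_mean.to_numpy(float)[some_det]
    ct[all_und] = sig.ct_ceiling
    status = df["status"].to_numpy(object).copy()
    status[some_det] = IMPUTED_FROM_REPLICATE
    status[all_und] = CEILING_UNDETERMINED

    df["ct"] = ct
    df["status"] = status
    df["undetermined"] = False
    return QcTable(data=df, params={"ct_ceiling": sig.ct_ceiling})


def gene_interval_stats(data: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean/SD/count over non-ceiling readings (the 95% interval
    basis). SD is the sample standard deviation (ddof=1)."""
    usable = data[data["status"] != CEILING_UNDETERMINED]
    stats = usable.groupby("gene")["ct"].agg(["mean", "std", "count"])
    stats["std"] = stats["std"].fillna(0.0)
    return stats


def flag_unreliable(
    table: QcTable,
    multiplier: float = 1.96,
    min_values: int = 3,
    stats: pd.DataFrame | None = None,
) -> QcTable:
    """Flag readings outside each transcript's central interval.

    A reading is unreliable when ``|ct - mean| > multiplier * SD`` for its
    gene, with mean/SD taken over all non-ceiling readings of that gene
    across samples (or supplied via ``stats`` to apply a stored interval).
    Ceiling readings are never re-flagged; genes with fewer than
    ``min_values`` usable readings are skipped with a warning. In the
    degenerate SD = 0 case equal values pass and any deviation flags.
    """
    df = table.data.copy()
    if stats is None:
        stats = gene_interval_stats(df)
    thin = stats.index[stats["count"] < min_values]
    if len(thin):
        warnings.warn(
            f"reliability interval skipped for genes with <{min_values} usable "
            f"values: {sorted(thin)}", stacklevel=2,
        )
    usable_stats = stats.drop(index=thin)
    m = df["gene"].map(usable_stats["mean"])
    s = df["gene"].map(usable_stats["std"])
    dev = (df["ct"] - m).abs()
    outlier = (dev > multiplier * s) & m.notna()
    flaggable = df["status"] != CEILING_UNDETERMINED
    df.loc[outlier & flaggable, "status"] = UNRELIABLE
    params = dict(table.params, interval_multiplier=multiplier)
    return QcTable(data=df, discards=table.discards.copy(), params=params)


def discard_samples(
    table: QcTable, sig: SignatureDefinition, max_bad_points: int = 1
) -> QcTable:
    """Apply the housekeeping-based sample discard rule.

    Replicate-level housekeeping data points (ACTB + HPRT pooled) with
    status ceiling-undetermined or unreliable are counted per sample; more
    than ``max_bad_points`` (i.e. two or more, by default) discards the
    sample. Samples missing a housekeeping gene entirely are discarded with
    reason ``housekeeping absent``.
    """
    df = table.data
    hk = df[df["gene"].isin(sig.housekeeping)]
    rows = []
    for sample, sub in hk.groupby("sample_id", sort=False):
        present = set(sub["gene"])
        missing = [g for g in sig.housekeeping if g not in present]
        if missing:
            rows.append((sample, f"housekeeping absent: {','.join(missing)}"))
            continue
        bad = sub[sub["status"].isin((CEILING_UNDETERMINED, UNRELIABLE))]
        if len(bad) > max_bad_points:
            pts = "; ".join(
                f"{r.gene} rep{r.replicate} {r.status}" for r in bad.itertuples()
            )
            rows.append((sample, f"{len(bad)} flagged housekeeping points: {pts}"))
    no_hk = sorted(set(df["sample_id"]) - set(hk["sample_id"]))
    rows += [(s, "housekeeping absent: " + ",".join(sig.housekeeping)) for s in no_hk]
    discards = pd.DataFrame(rows, columns=["sample_id", "reason"]).sort_values(
        "sample_id", kind="stable", ignore_index=True
    )
    return QcTable(data=df.copy(), discards=discards, params=dict(table.params))


def compute_delta_ct(
    table: QcTable,
    sig: SignatureDefinition,
    collapse: str = "mean",
    ceiling_policy: str = "retain",
    genes: tuple[str, ...] | None = None,
) -> DeltaCtResult:
    """Collapse replicates and normalize against the reference gene(s).

    ``collapse='mean'`` averages usable replicates, excluding unreliable
    readings; ``'keep-all'`` retains them. ``ceiling_policy='retain'`` keeps
    ceiling-imputed readings as measurements (the instrument's censoring
    value); ``'missing'`` drops them. Cells with no usable replicate are NaN.
    Samples whose reference gene has no usable reading are excluded with a
    warning (normally already discarded).
    """
    if collapse not in ("mean", "keep-all"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    if ceiling_policy not in ("retain", "missing"):
        raise ValueError(f"unknown ceiling policy {ceiling_policy!r}")
    df = table.retained()
    usable = df["status"].isin((OK, IMPUTED_FROM_REPLICATE))
    if collapse == "keep-all":
        usable |= df["status"] == UNRELIABLE
    if ceiling_policy == "retain":
        usable |= df["status"] == CEILING_UNDETERMINED
    df = df[usable]

    ref = df[df["gene"].isin(sig.reference_genes)]
    ref_means = ref.groupby("sample_id")["ct"].mean()

    genes = tuple(genes if genes is not None else sig.genes)
    sub = df[df["gene"].isin(genes)]
    collapsed = sub.groupby(["sample_id", "gene"])["ct"].mean().unstack("gene")
    samples = sorted(set(table.retained()["sample_id"]))
    collapsed = collapsed.reindex(index=samples, columns=list(genes))

    no_ref = [s for s in samples if s not in ref_means.index]
    if no_ref:
        warnings.warn(
            f"samples without usable reference-gene Ct excluded from dCt: {no_ref}",
            stacklevel=2,
        )
        collapsed = collapsed.drop(index=no_ref)
    matrix = collapsed.sub(ref_means.reindex(collapsed.index), axis=0)
    matrix.index.name = "sample_id"
    return DeltaCtResult(
        matrix=matrix,
        reference_means=ref_means.reindex(collapsed.index),
        reference_genes=tuple(sig.reference_genes),
        params=dict(table.params, collapse=collapse, ceiling_policy=ceiling_policy),
    )


def run_qc(
    table: pd.DataFrame,
    sig: SignatureDefinition,
    interval_multiplier: float = 1.96,
    strict: bool = True,
) -> QcTable:
    """Reconcile -> flag -> discard, the full QC chain."""
    qc = reconcile_replicates(table, sig, strict=strict)
    qc = flag_unreliable(qc, multiplier=interval_multiplier)
    return discard_samples(qc, sig)


class CtQualityControl(BaseEstimator, TransformerMixin):
    """Transformer wrapping the Ct QC chain.

    ``fit`` learns the per-transcript reliability intervals from a cohort
    (after replicate reconciliation); ``transform`` reconciles, flags
    against the learned intervals and applies the sample discard rule.
    ``fit_transform`` on one cohort reproduces the in-sample procedure.
    """

    def __init__(
        self,
        signature: SignatureDefinition | None = None,
        interval_multiplier: float = 1.96,
        strict: bool = True,
    ):
        self.signature = signature
        self.interval_multiplier = interval_multiplier
        self.strict = strict

    def _sig(self) -> SignatureDefinition:
        if self.signature is None:
            raise ValueError("signature must be set before use")
        return self.signature

    def fit(self, X: pd.DataFrame, y=None):
        qc = reconcile_replicates(X, self._sig(), strict=self.strict)
        self.gene_stats_ = gene_interval_stats(qc.data)
        self.n_samples_seen_ = X["sample_id"].nunique()
        return self

    def transform(self, X: pd.DataFrame) -> QcTable:
        qc = reconcile_replicates(X, self._sig(), strict=self.strict)
        qc = flag_unreliable(qc, multiplier=self.interval_multiplier,
                             stats=self.gene_stats_)
        return discard_samples(qc, self._sig())


class DeltaCtNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from a QC'd Ct table to the dCt matrix."""

    def __init__(
        self,
        signature: SignatureDefinition | None = None,
        collapse: str = "mean",
        ceiling_policy: str = "retain",
    ):
        self.signature = signature
        self.collapse = collapse
        self.ceiling_policy = ceiling_policy

    def fit(self, X: QcTable, y=None):
        if self.signature is None:
            raise ValueError("signature must be set before use")
        self.reference_genes_ = tuple(self.signature.reference_genes)
        return self

    def transform(self, X: QcTable) -> pd.DataFrame:
        result = compute_delta_ct(
            X, self.signature, collapse=self.collapse,
            ceiling_policy=self.ceiling_policy,
        )
        self.reference_means_ = result.reference_means
        return result.matrix
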