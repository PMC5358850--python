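"""Per-sample signature risk score.

The risk score is the mean dCt of the genes down-regulated in node-positive
tumors minus the mean dCt of the genes up-regulated in node-positive tumors.
Because dCt falls as expression rises, higher scores correspond to an
expression pattern matching node-positive disease; no sign flip is applied.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import DeltaCtResult, SignatureDefinition


def compute_risk_score(
    dct: pd.DataFrame | DeltaCtResult,
    sig: SignatureDefinition,
    min_genes: int = 1,
    strict: bool = False,
) -> pd.DataFrame:
    """Score every sample of a dCt matrix.

    Missing genes are dropped from their direction mean (each mean needs at
    least ``min_genes`` genes, else the score is missing with a reason);
    ``strict`` additionally requires every signature gene to carry a
    direction. Returns a frame indexed by sample with columns
    ``risk_score``, ``n_down_genes_used``, ``n_up_genes_used``, ``reason``.
    """
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    sig.validate_for_scoring(strict=strict)
    down = [g for g in sig.down_genes if g in dct.columns]
    up = [g for g in sig.up_genes if g in dct.columns]
    if not down or not up:
        raise ValueError(
            "dCt matrix lacks all genes of one direction "
            f"(down present: {down}, up present: {up})"
        )
    n_down = dct[down].notna().sum(axis=1)
    n_up = dct[up].notna().sum(axis=1)
    score = dct[down].mean(axis=1) - dct[up].mean(axis=1)
    ok = (n_down >= min_genes) & (n_up >= min_genes)
    if strict:
        ok &= (n_down == len(sig.down_genes)) & (n_up == len(sig.up_genes))
    out = pd.DataFrame(
        {
            "risk_score": score.where(ok, np.nan),
            "n_down_genes_used": n_down.astype(int),
            "n_up_genes_used": n_up.astype(int),
        },
        index=dct.index,
    )
    out["reason"] = np.where(
        ok, "", "fewer than required genes in a direction group"
    )
    out.index.name = "sample_id"
    return out


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Transformer computing signature risk scores from a dCt matrix.

    Accepts a samples x genes :class:`~pandas.DataFrame` (or
    :class:`~qpcrsig.model.DeltaCtResult`) and returns the risk-score table.
    """

    def __init__(self, signature: SignatureDefinition | None = None,
                 min_genes: int = 1, strict: bool = False):
        self.signature = signature
        self.min_genes = min_genes
        self.strict = strict

    def fit(self, X, y=None):
        if self.signature is None:
            raise ValueError("signature must be set before use")
        self.signature.validate_for_scoring(strict=self.strict)
        self.down_genes_ = self.signature.down_genes
        self.up_genes_ = self.signature.up_genes
        return self

    def transform(self, X) -> pd.DataFrame:
        return compute_risk_score(
            X, self.signature, min_genes=self.min_genes, strict=self.strict
        )
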