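"""Shared data model for qRT-PCR signature validation.

Tabular data is carried in :class:`pandas.DataFrame` objects with the column
conventions defined here; small typed containers wrap them where extra state
(QC parameters, discard decisions, reference means) must travel alongside.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

#: Long-format Ct table columns (``well`` is optional).
CT_COLUMNS = ("sample_id", "gene", "replicate", "plate_id", "ct")

#: Key that must be unique within a Ct table.
CT_KEY = ("sample_id", "gene", "replicate")

# Per-measurement QC statuses.
OK = "ok"
IMPUTED_FROM_REPLICATE = "imputed_from_replicate"
CEILING_UNDETERMINED = "ceiling_undetermined"
UNRELIABLE = "unreliable"
QC_STATUSES = (OK, IMPUTED_FROM_REPLICATE, CEILING_UNDETERMINED, UNRELIABLE)

# Gene direction labels: expression behaviour in lymph-node-positive tumors.
UP_IN_POS = "up_in_pos"
DOWN_IN_POS = "down_in_pos"
UNSPECIFIED = "unspecified"
DIRECTIONS = (UP_IN_POS, DOWN_IN_POS, UNSPECIFIED)

POSITIVE = "positive"
NEGATIVE = "negative"


class SignatureError(ValueError):
    """Invalid signature definition or direction configuration."""


@dataclass(frozen=True)
class SignatureDefinition:
    """A gene-expression signature with per-gene direction labels.

    Parameters
    ----------
    genes
        Ordered signature gene symbols (opaque, case-sensitive strings).
    direction
        Map gene -> {up_in_pos, down_in_pos, unspecified}; genes absent from
        the map are treated as unspecified.
    housekeeping
        Genes used for sample-quality gating (not scored).
    reference_genes
        Genes whose per-sample mean Ct is the dCt reference.
    ct_ceiling
        Ct assigned when both replicates of a well pair are undetermined.
    plate_control
        Optional control-sample label excluded from statistics.
    aliases
        Optional synonym map (e.g. ``FAM36A -> FAM36A/COX20``) applied when
        resolving gene symbols in external tables.
    """

    genes: tuple[str, ...]
    direction: Mapping[str, str] = field(default_factory=dict)
    housekeeping: tuple[str, ...] = ("ACTB", "HPRT")
    reference_genes: tuple[str, ...] = ("ACTB",)
    ct_ceiling: float = 35.0
    plate_control: str | None = None
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "housekeeping", tuple(self.housekeeping))
        object.__setattr__(self, "reference_genes", tuple(self.reference_genes))
        if not self.genes:
            raise SignatureError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise SignatureError("duplicate genes in signature")
        overlap = set(self.genes) & set(self.housekeeping)
        if overlap:
            raise SignatureError(
                f"genes cannot be both signature and housekeeping: {sorted(overlap)}"
            )
        bad = {g: d for g, d in self.direction.items() if d not in DIRECTIONS}
        if bad:
            raise SignatureError(f"unknown direction labels: {bad}")
        if not self.ct_ceiling > 0:
            raise SignatureError("ct_ceiling must be positive")

    def direction_of(self, gene: str) -> str:
        return self.direction.get(gene, UNSPECIFIED)

    @property
    def up_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.direction_of(g) == UP_IN_POS)

    @property
    def down_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.direction_of(g) == DOWN_IN_POS)

    @property
    def scored_genes(self) -> tuple[str, ...]:
        """Genes with a known direction, in signature order."""
        return tuple(g for g in self.genes if self.direction_of(g) != UNSPECIFIED)

    def validate_for_scoring(self, strict: bool = False) -> None:
        """Check the signature can produce a risk score.

        With ``strict`` every gene must carry a direction; otherwise at least
        one gene per direction is required.
        """
        if strict:
            unspec = [g for g in self.genes if self.direction_of(g) == UNSPECIFIED]
            if unspec:
                raise SignatureError(f"genes without direction: {unspec}")
        if not self.up_genes or not self.down_genes:
            raise SignatureError(
                "scoring requires at least one gene in each direction "
                f"(up={len(self.up_genes)}, down={len(self.down_genes)})"
            )

    def resolve(self, symbol: str) -> str:
        """Map an external symbol onto the signature's spelling via aliases."""
        return self.aliases.get(symbol, symbol)


@dataclass
class QcTable:
    """A reconciled/flagged Ct table plus sample discard decisions.

    ``data`` keeps every input measurement (QC never drops rows; discarded
    samples are listed in ``discards`` and excluded downstream).
    """

    data: pd.DataFrame
    discards: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    params: dict = field(default_factory=dict)

    @property
    def discarded_samples(self) -> list[str]:
        return list(self.discards["sample_id"])

    def flag_counts(self) -> pd.Series:
        return self.data["status"].value_counts().reindex(QC_STATUSES, fill_value=0)

    def retained(self) -> pd.DataFrame:
        """Measurements of samples that survived QC."""
        return self.data[~self.data["sample_id"].isin(self.discarded_samples)]


@dataclass
class DeltaCtResult:
    """Samples x genes dCt matrix plus the reference used to build it.

    dCt = collapsed gene Ct - per-sample mean reference-gene Ct; missing
    cells are NaN.
    """

    matrix: pd.DataFrame
    reference_means: pd.Series
    reference_genes: tuple[str, ...]
    params: dict = field(default_factory=dict)


def signature_to_dict(sig: SignatureDefinition) -> dict:
    d = dataclasses.asdict(sig)
    d["genes"] = list(sig.genes)
    d["housekeeping"] = list(sig.housekeeping)
    d["reference_genes"] = list(sig.reference_genes)
    d["direction"] = dict(sig.direction)
    d["aliases"] = dict(sig.aliases)
    return d


def normalize_ln_status(values: Sequence) -> pd.Series:
    """Map assorted lymph-node status spellings onto {positive, negative}.

    Accepts LN+/LN-, pN0/pN1-3 style stage codes, 0/1 and yes/no spellings;
    unrecognised or missing entries become NaN (samples without a status are
    excluded from statistics but still QC'd).
    """
    mapping = {
        "positive": POSITIVE, "pos": POSITIVE, "ln+": POSITIVE, "1": POSITIVE,
        "n1": POSITIVE, "n2": POSITIVE, "n3": POSITIVE, "n1-3": POSITIVE,
        "pn1": POSITIVE, "pn2": POSITIVE, "pn3": POSITIVE, "yes": POSITIVE,
        "true": POSITIVE,
        "negative": NEGATIVE, "neg": NEGATIVE, "ln-": NEGATIVE, "0": NEGATIVE,
        "n0": NEGATIVE, "pn0": NEGATIVE, "no": NEGATIVE, "false": NEGATIVE,
    }
    ser = pd.Series(values)
    out = ser.astype("string").str.strip().str.lower().map(mapping)
    return out.astype(object)
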