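"""Readers and writers for Ct tables, clinical annotations, signature
configurations and expression matrices.

All files are plain delimited text (CSV by default, TSV auto-detected by
extension) or YAML/JSON for configuration. Undetermined Ct readings are
carried through as a configurable instrument token (default ``Undetermined``,
matched case-insensitively) and are never silently coerced to numbers.
"""
from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    CT_COLUMNS,
    CT_KEY,
    DIRECTIONS,
    UNSPECIFIED,
    SignatureDefinition,
    SignatureError,
    normalize_ln_status,
)

DEFAULT_UNDETERMINED_TOKEN = "Undetermined"


class CtParseError(ValueError):
    """A Ct table violates the format contract (duplicate key, bad value)."""


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_ct_table(
    path,
    sep: str | None = None,
    undetermined_token: str = DEFAULT_UNDETERMINED_TOKEN,
) -> pd.DataFrame:
    """Read a long-format Ct table.

    Expected columns: ``sample_id, gene, replicate, plate_id, ct`` (plus an
    optional ``well``). The returned frame stores ``ct`` as float with NaN
    where the instrument reported the undetermined token, and a boolean
    ``undetermined`` column.

    Raises
    ------
    CtParseError
        On a duplicated (sample_id, gene, replicate) key or a ct entry that
        is neither numeric nor the undetermined token.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise CtParseError(f"{path}: missing columns {missing}")

    raw = df["ct"].str.strip()
    undet = raw.str.lower() == undetermined_token.lower()
    ct = pd.to_numeric(raw.where(~undet), errors="coerce")
    bad = ct.isna() & ~undet
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CtParseError(
            f"{path}: row {i + 2}: ct value {raw.iloc[i]!r} is neither numeric "
            f"nor the undetermined token {undetermined_token!r}"
        )
    if (ct <= 0).any():
        i = int(np.flatnonzero((ct <= 0).to_numpy())[0])
        raise CtParseError(f"{path}: row {i + 2}: non-positive ct {ct.iloc[i]}")

    out = df.copy()
    out["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    if (out["replicate"] < 1).any():
        raise CtParseError(f"{path}: replicate indices must be >= 1")
    out["ct"] = ct.astype(float)
    out["undetermined"] = undet.to_numpy()

    dup = out.duplicated(subset=list(CT_KEY), keep=False)
    if dup.any():
        key = out.loc[dup, list(CT_KEY)].iloc[0].tolist()
        raise CtParseError(f"{path}: duplicated (sample_id, gene, replicate) key {key}")
    return out


def write_ct_table(
    table: pd.DataFrame,
    path,
    sep: str | None = None,
    undetermined_token: str = DEFAULT_UNDETERMINED_TOKEN,
) -> None:
    """Write a Ct table, restoring the undetermined token for NaN readings."""
    path = Path(path)
    cols = [c for c in (*CT_COLUMNS, "well") if c in table.columns]
    out = table[cols].copy()
    ct = out["ct"].astype(object)
    if "undetermined" in table.columns:
        ct[table["undetermined"].to_numpy()] = undetermined_token
    else:
        ct[out["ct"].isna()] = undetermined_token
    out["ct"] = ct
    out.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_signature_config(path, strict: bool = False) -> SignatureDefinition:
    """Read a signature definition from YAML or JSON.

    Recognised keys: ``genes`` (required), ``direction`` (map gene ->
    up_in_pos / down_in_pos / unspecified), ``housekeeping``,
    ``reference_genes``, ``ct_ceiling``, ``plate_control``, ``aliases``.
    With ``strict`` every gene must carry a non-unspecified direction.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return signature_from_dict(cfg, strict=strict)


def signature_from_dict(cfg: dict, strict: bool = False) -> SignatureDefinition:
    if not isinstance(cfg, dict) or "genes" not in cfg:
        raise SignatureError("signature config must be a mapping with a 'genes' key")
    direction = {g: str(d).lower() for g, d in (cfg.get("direction") or {}).items()}
    unknown = sorted(set(direction) - set(cfg["genes"]))
    if unknown:
        raise SignatureError(f"direction entries for genes not in signature: {unknown}")
    for g, d in direction.items():
        if d not in DIRECTIONS:
            raise SignatureError(f"gene {g}: unknown direction {d!r}")
    sig = SignatureDefinition(
        genes=tuple(cfg["genes"]),
        direction=direction,
        housekeeping=tuple(cfg.get("housekeeping", ("ACTB", "HPRT"))),
        reference_genes=tuple(cfg.get("reference_genes", ("ACTB",))),
        ct_ceiling=float(cfg.get("ct_ceiling", 35.0)),
        plate_control=cfg.get("plate_control"),
        aliases=dict(cfg.get("aliases") or {}),
    )
    if strict:
        unspec = [g for g in sig.genes if sig.direction_of(g) == UNSPECIFIED]
        if unspec:
            raise SignatureError(f"strict mode: genes without direction: {unspec}")
    return sig


def default_signature() -> SignatureDefinition:
    """The shipped 20-gene lymph-node-metastasis signature.

    Eight direction labels are documented (five up- and three down-regulated
    in node-positive disease); the remaining twelve are left unspecified and
    must be supplied before scoring.
    """
    ref = importlib.resources.files("qpcrsig.data") / "default_signature.yaml"
    return signature_from_dict(yaml.safe_load(ref.read_text()))


def read_annotation(path, sep: str | None = None, ln_column: str = "ln_status") -> pd.DataFrame:
    """Read a clinical annotation table keyed by ``sample_id``.

    The lymph-node status column is normalised to {positive, negative}
    (NaN when unknown). Remaining columns are covariates; empty strings in
    non-numeric covariates become the explicit level ``Unknown``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns or ln_column not in df.columns:
        raise ValueError(f"{path}: need columns sample_id and {ln_column}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample_id")
    out = df.copy()
    out["ln_status"] = normalize_ln_status(df[ln_column]).to_numpy()
    for col in out.columns:
        if col in ("sample_id", "ln_status"):
            continue
        if out[col].dtype == object:
            vals = out[col].astype("string").str.strip()
            out[col] = vals.fillna("Unknown").replace("", "Unknown").astype(object)
    return out


def read_expression_matrix(
    matrix_path, groups_path, sep: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes x samples expression matrix and its sample-group map.

    The matrix file has genes as rows (first column = gene symbol); the
    groups file has columns ``sample_id`` and ``group``.
    """
    mat = pd.read_csv(matrix_path, sep=sep or _sep_for(matrix_path), index_col=0)
    if mat.index.duplicated().any():
        raise ValueError(f"{matrix_path}: duplicated gene rows")
    if mat.columns.duplicated().any():
        raise ValueError(f"{matrix_path}: duplicated sample columns")
    grp = pd.read_csv(groups_path, sep=sep or _sep_for(groups_path), dtype=str)
    if not {"sample_id", "group"} <= set(grp.columns):
        raise ValueError(f"{groups_path}: need columns sample_id and group")
    groups = grp.set_index("sample_id")["group"]
    unknown = [s for s in mat.columns if s not in groups.index]
    if unknown:
        raise ValueError(f"samples without group label: {unknown[:5]}")
    return mat, groups.loc[list(mat.columns)]


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")
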