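"""Validation statistics: ROC/AUC with DeLong confidence intervals, per-gene
logistic odds ratios, Mann-Whitney two-group tests, Pearson correlation with
complete-linkage clustering, and cohort contingency comparisons.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps
import statsmodels.api as sm
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import NEGATIVE, POSITIVE, DeltaCtResult


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    """AUC with CI and the full ROC step curve."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    ci_method: str = "delong"
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "ci_method": self.ci_method, "note": self.note,
        }


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biuf":
        y = arr.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("numeric labels must be 0/1")
        return y
    mapped = pd.Series(arr).map({POSITIVE: 1, NEGATIVE: 0})
    if mapped.isna().any():
        raise ValueError("labels must be positive/negative or 0/1")
    return mapped.to_numpy(int)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placement values."""
    m, n = len(pos), len(neg)
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v01 = (tz[:m] - tx) / n          # placements of positives among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placements of negatives among positives
    auc = float(v01.mean())
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return auc, s01 / m + s10 / n


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """AUC of a continuous score against a binary outcome.

    Ties receive half credit (midranks). The 95% CI is DeLong (default) or a
    seeded stratified percentile bootstrap. Constant scores give AUC 0.5
    with a degenerate CI, flagged in ``note``.
    """
    scores = np.asarray(scores, float)
    y = _as_binary_labels(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    keep = ~np.isnan(scores)
    scores, y = scores[keep], y[keep]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"both classes required (n_pos={n_pos}, n_neg={n_neg})")

    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    pos, neg = scores[y == 1], scores[y == 0]
    auc, var = _delong_variance(pos, neg)

    note = ""
    if np.ptp(scores) == 0:
        note = "constant scores: degenerate CI"
        lo = hi = auc
        return RocResult(auc, lo, hi, n_pos, n_neg, fpr, tpr, thr, ci_method, note)

    if ci_method == "delong":
        z = sps.norm.ppf(1 - alpha / 2)
        se = np.sqrt(var)
        lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
        if var == 0:
            note = "zero DeLong variance: degenerate CI"
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            p = pos[rng.integers(0, n_pos, n_pos)]
            q = neg[rng.integers(0, n_neg, n_neg)]
            reps[b], _ = _delong_variance(p, q)
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(float(auc), float(lo), float(hi), n_pos, n_neg,
                     fpr, tpr, thr, ci_method, note)


def subgroup_evaluate(scores, labels, keep, **kwargs) -> RocResult:
    """ROC analysis restricted to samples passing a filter.

    ``keep`` is a boolean mask aligned with ``scores`` (or a predicate
    applied elementwise to the score index when given pandas input).
    """
    scores = pd.Series(scores)
    labels = pd.Series(np.asarray(labels), index=scores.index)
    if callable(keep):
        mask = scores.index.map(keep).astype(bool)
    else:
        mask = np.asarray(keep, bool)
    if mask.sum() == 0:
        raise ValueError("empty subgroup")
    return roc_auc(scores[mask], labels[mask], **kwargs)


# ---------------------------------------------------------------------------
# Logistic regression


def _or_row(gene: str, res, n: int, note: str = "") -> dict:
    beta = res.params[-1]
    se = res.bse[-1]
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        return {
            "gene": gene,
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - z * se)),
            "ci_high": float(np.exp(beta + z * se)),
            "p_value": float(res.pvalues[-1]),
            "n_used": n,
            "note": note,
        }


def univariate_or(dct, ann: pd.DataFrame, gene: str) -> dict:
    """Per-gene logistic odds ratio for node-positive disease.

    Maximum-likelihood logistic regression of LN status (positive = 1) on
    the gene's dCt, per cycle; OR = exp(beta) with Wald 95% CI. Complete
    separation yields a flagged row with infinite CI rather than an
    exception; a constant predictor yields an error row.
    """
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    merged = pd.DataFrame({"x": dct[gene]}).join(
        ann.set_index("sample_id")["ln_status"] if "sample_id" in ann.columns
        else ann["ln_status"]
    )
    merged = merged.dropna(subset=["x", "ln_status"])
    y = _as_binary_labels(merged["ln_status"])
    x = merged["x"].to_numpy(float)
    n = len(x)
    for cls, lbl in ((1, "positive"), (0, "negative")):
        if (y == cls).sum() < 2:
            raise ValueError(f"need >=2 {lbl} samples with dCt for {gene}")
    if np.ptp(x) == 0:
        return {
            "gene": gene, "odds_ratio": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "p_value": np.nan, "n_used": n,
            "note": "constant predictor",
        }
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
    row = _or_row(gene, res, n)
    if not np.isfinite(res.bse[-1]) or res.bse[-1] > 1e3:
        row.update(ci_low=0.0, ci_high=np.inf, note="possible complete separation")
    return row


def or_table(dct, ann: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Univariate OR rows for each gene of a dCt matrix."""
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    genes = list(genes) if genes is not None else list(dct.columns)
    rows = []
    for g in genes:
        try:
            rows.append(univariate_or(dct, ann, g))
        except ValueError as exc:
            rows.append({"gene": g, "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "n_used": 0,
                         "note": str(exc)})
    return pd.DataFrame(rows, columns=["gene", "odds_ratio", "ci_low",
                                       "ci_high", "p_value", "n_used", "note"])


def multivariate_model(dct, ann: pd.DataFrame, genes) -> tuple[RocResult, pd.DataFrame]:
    """Joint logistic model of several genes; AUC of the in-sample linear
    predictor. Rank-deficient (collinear) predictor sets trigger a warning
    and a regularised fallback fit."""
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    genes = list(genes)
    merged = dct[genes].join(
        ann.set_index("sample_id")["ln_status"] if "sample_id" in ann.columns
        else ann["ln_status"]
    ).dropna()
    y = _as_binary_labels(merged["ln_status"])
    Xmat = merged[genes].to_numpy(float)
    if np.linalg.matrix_rank(Xmat - Xmat.mean(0)) < len(genes):
        warnings.warn("collinear predictors in multivariate model", stacklevel=2)
    X = sm.add_constant(Xmat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse, pvals = res.params, res.bse, res.pvalues
        except Exception:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            params = res.params
            try:
                bse, pvals = res.bse, res.pvalues
            except Exception:
                bse = np.full_like(params, np.nan)
                pvals = np.full_like(params, np.nan)
    linpred = X @ params
    roc = roc_auc(linpred, y)
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        coefs = pd.DataFrame({
            "term": ["intercept"] + genes,
            "coef": params,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvals,
        })
    return roc, coefs


# ---------------------------------------------------------------------------
# Two-group tests


def two_group_test(x, y, exact_limit: int = 400) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing two groups of values.

    U is reported for the first group. The exact null distribution is used
    when ``n1*n2 <= exact_limit`` and there are no ties; otherwise the
    tie-corrected normal approximation (with continuity correction). All
    values tied across both groups gives p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both groups: p = 1", stacklevel=2)
        return float(len(x) * len(y) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= exact_limit and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def expression_test_table(matrix: pd.DataFrame, groups: pd.Series,
                          pos_label: str, neg_label: str,
                          genes=None) -> pd.DataFrame:
    """Per-gene Mann-Whitney tests on a genes x samples expression matrix."""
    genes = list(genes) if genes is not None else list(matrix.index)
    pos = groups.index[groups == pos_label]
    neg = groups.index[groups == neg_label]
    rows = []
    for g in genes:
        vals = matrix.loc[g]
        u, p = two_group_test(vals[pos], vals[neg])
        rows.append({
            "gene": g, "U": u, "p_value": p,
            "median_pos": float(np.nanmedian(vals[pos])),
            "median_neg": float(np.nanmedian(vals[neg])),
            "n_pos": int(vals[pos].notna().sum()),
            "n_neg": int(vals[neg].notna().sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation / clustering


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with complete-linkage clustering on
    d = 1 - r."""

    corr: pd.DataFrame
    linkage: np.ndarray | None
    clusters: pd.Series
    cut_height: float
    dropped: list[str] = field(default_factory=list)


def correlation_cluster(
    dct, min_samples: int = 3, cut_height: float = 0.34
) -> CorrelationResult:
    """Gene-gene Pearson correlation with hierarchical clustering.

    Correlations use pairwise-complete observations. Genes that are constant
    or lack ``min_samples`` complete pairs with some partner are excluded
    from clustering with a warning. The default cut height 0.34 groups genes
    correlated at r >= 0.66.
    """
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    if dct.shape[0] < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    corr = dct.corr(method="pearson", min_periods=min_samples)
    np.fill_diagonal(corr.values, 1.0)

    constant = [g for g in dct.columns
                if dct[g].dropna().nunique() <= 1]
    incomplete = [g for g in corr.columns
                  if corr[g].isna().any() and g not in constant]
    dropped = constant + incomplete
    if dropped:
        warnings.warn(
            f"genes excluded from clustering (constant or insufficient "
            f"overlap): {dropped}", stacklevel=2,
        )
        corr.loc[constant, :] = np.nan
        corr.loc[:, constant] = np.nan
        np.fill_diagonal(corr.values, 1.0)

    keep = [g for g in corr.columns if g not in dropped]
    if len(keep) >= 2:
        sub = corr.loc[keep, keep].to_numpy()
        dist = squareform(np.clip(1.0 - sub, 0.0, None), checks=False)
        Z = sch.linkage(dist, method="complete")
        labels = sch.fcluster(Z, t=cut_height, criterion="distance")
        clusters = pd.Series(labels, index=keep, name="cluster")
    else:
        Z = None
        clusters = pd.Series(dtype=int, name="cluster")
    return CorrelationResult(corr=corr, linkage=Z, clusters=clusters,
                             cut_height=cut_height, dropped=dropped)


# ---------------------------------------------------------------------------
# Cohort (Table-1 style) comparisons


def round_half_away(x: float) -> int:
    """Round half away from zero (5 -> nearest away), as clinical tables do."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class CohortRow:
    """One covariate's two-group comparison."""

    covariate: str
    kind: str                      # categorical | continuous
    table: pd.DataFrame
    test_name: str
    statistic: float
    p_value: float


def cohort_compare(
    ann: pd.DataFrame,
    covariate: str,
    group_col: str = "ln_status",
    kind: str | None = None,
    unknown_level: str = "Unknown",
) -> CohortRow:
    """Compare a covariate between the two LN groups.

    Categorical covariates get per-group counts and percentages (computed
    over the full group including Unknown, rounded half away from zero);
    the test (Fisher's exact for 2x2, chi-square otherwise) excludes the
    Unknown level. Continuous covariates get group mean/min/max and a
    two-sided Mann-Whitney U test. A covariate that is entirely Unknown
    yields a descriptive row with no test.
    """
    df = ann[[group_col, covariate]].copy()
    df = df[df[group_col].isin((POSITIVE, NEGATIVE))]
    if kind is None:
        kind = ("continuous"
                if pd.api.types.is_numeric_dtype(df[covariate]) else "categorical")

    if kind == "continuous":
        groups = {g: df.loc[df[group_col] == g, covariate].dropna()
                  for g in (NEGATIVE, POSITIVE)}
        rows = {
            g: {"n": len(v), "mean": v.mean() if len(v) else np.nan,
                "min": v.min() if len(v) else np.nan,
                "max": v.max() if len(v) else np.nan}
            for g, v in groups.items()
        }
        table = pd.DataFrame(rows).T
        if min(len(v) for v in groups.values()) == 0:
            return CohortRow(covariate, kind, table, "none", np.nan, np.nan)
        u, p = two_group_test(groups[NEGATIVE], groups[POSITIVE])
        return CohortRow(covariate, kind, table, "mann-whitney", u, p)

    vals = df[covariate].astype(object).where(df[covariate].notna(), unknown_level)
    counts = pd.crosstab(vals, df[group_col])
    for g in (NEGATIVE, POSITIVE):
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[[NEGATIVE, POSITIVE]]
    totals = counts.sum(axis=0)  # full group size including Unknown
    table = counts.copy()
    for g in (NEGATIVE, POSITIVE):
        table[f"pct_{g}"] = [
            round_half_away(100.0 * c / totals[g]) if totals[g] else 0
            for c in counts[g]
        ]

    known = counts.drop(index=unknown_level, errors="ignore")
    known = known.loc[known.sum(axis=1) > 0]
    if known.empty or known.shape[0] < 2:
        return CohortRow(covariate, kind, table, "none", np.nan, np.nan)
    if known.shape == (2, 2):
        odds, p = sps.fisher_exact(known.to_numpy(), alternative="two-sided")
        return CohortRow(covariate, kind, table, "fisher", float(odds), float(p))
    chi2, p, _, _ = sps.chi2_contingency(known.to_numpy())
    return CohortRow(covariate, kind, table, "chi-square", float(chi2), float(p))


def cohort_table(ann: pd.DataFrame, covariates, **kwargs) -> list[CohortRow]:
    return [cohort_compare(ann, c, **kwargs) for c in covariates]


def group_means(dct, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean dCt in each LN group (bar-plot style summary)."""
    if isinstance(dct, DeltaCtResult):
        dct = dct.matrix
    status = (ann.set_index("sample_id")["ln_status"]
              if "sample_id" in ann.columns else ann["ln_status"])
    status = status.reindex(dct.index)
    out = {}
    for g in (NEGATIVE, POSITIVE):
        out[f"mean_dct_{g}"] = dct[status == g].mean()
        out[f"n_{g}"] = dct[status == g].notna().sum()
    res = pd.DataFrame(out)
    res.index.name = "gene"
    return res
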