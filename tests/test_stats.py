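import itertools
import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings, strategies as st

from qpcrsig import (
    cohort_compare,
    correlation_cluster,
    multivariate_model,
    or_table,
    roc_auc,
    subgroup_evaluate,
    two_group_test,
    univariate_or,
)
from qpcrsig.stats import round_half_away


# ---------------------------------------------------------------------------
# Oracles


def auc_by_pair_counting(pos, neg):
    """Brute-force AUC: wins + half credit for ties over all pairs."""
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def mwu_exact_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments."""
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    mn = m * n

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    u_obs = u_of(range(m))
    lo, hi = min(u_obs, mn - u_obs), max(u_obs, mn - u_obs)
    us = [u_of(c) for c in itertools.combinations(range(m + n), m)]
    return u_obs, sum(u <= lo or u >= hi for u in us) / len(us)


def complete_linkage_bruteforce(dist: np.ndarray):
    """Merge heights of complete-linkage agglomeration, by direct search."""
    clusters = [{i} for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] \
            + [clusters[a] | clusters[b]]
    return heights


# ---------------------------------------------------------------------------
# ROC / AUC


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([2, 3, 0, 1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_interleaved_scores_pair_counting(self):
        # POS {1,3} vs NEG {0,2}: 3 of 4 pairs won
        r = roc_auc([1, 3, 0, 2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(3 / 4, abs=1e-12)

    def test_identical_multisets_give_half(self):
        r = roc_auc([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(0.5, abs=1e-12)

    def test_curve_is_a_valid_step_function_matching_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        r = roc_auc(scores, labels)
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-10)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.data())
    def test_auc_equals_pair_counting(self, data):
        n_pos = data.draw(st.integers(1, 10))
        n_neg = data.draw(st.integers(1, 10))
        tie_prone = data.draw(st.booleans())
        elems = st.integers(0, 4) if tie_prone else st.floats(
            -5, 5, allow_nan=False)
        pos = data.draw(st.lists(elems, min_size=n_pos, max_size=n_pos))
        neg = data.draw(st.lists(elems, min_size=n_neg, max_size=n_neg))
        r = roc_auc(np.r_[pos, neg], np.r_[np.ones(n_pos), np.zeros(n_neg)])
        assert r.auc == pytest.approx(auc_by_pair_counting(pos, neg), abs=1e-12)

    def test_constant_scores_flagged_degenerate(self):
        r = roc_auc([1.0, 1.0, 1.0], [1, 0, 0])
        assert r.auc == 0.5
        assert "degenerate" in r.note

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])

    def test_bootstrap_ci_is_seeded_and_brackets_auc(self):
        rng = np.random.default_rng(0)
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(40), np.zeros(60)]
        r1 = roc_auc(scores, labels, ci_method="bootstrap", n_boot=500, seed=5)
        r2 = roc_auc(scores, labels, ci_method="bootstrap", n_boot=500, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low < r1.auc < r1.ci_high

    def test_delong_ci_matches_pROC(self, tmp_path):
        # Independent oracle: R's pROC DeLong CI on the same data.
        rng = np.random.default_rng(11)
        pos = rng.normal(0.8, 1, 25)
        neg = rng.normal(0.0, 1, 35)
        r = roc_auc(np.r_[pos, neg], np.r_[np.ones(25), np.zeros(35)])
        csv = tmp_path / "d.csv"
        pd.DataFrame({"score": np.r_[pos, neg],
                      "y": np.r_[np.ones(25), np.zeros(35)]}).to_csv(
            csv, index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "ci <- ci.auc(roc(d$y, d$score, quiet=TRUE), method='delong');"
            "cat(sprintf('%.10f %.10f %.10f', ci[1], ci[2], ci[3]))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        lo, auc, hi = map(float, out.stdout.split())
        assert r.auc == pytest.approx(auc, abs=1e-9)
        assert r.ci_low == pytest.approx(lo, abs=1e-6)
        assert r.ci_high == pytest.approx(hi, abs=1e-6)


class TestSubgroup:
    def _scored(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=40),
                           index=[f"S{i}" for i in range(40)])
        labels = pd.Series(np.r_[np.ones(15), np.zeros(25)].astype(int),
                           index=scores.index)
        return scores, labels

    def test_identity_filter_matches_full_analysis(self):
        scores, labels = self._scored()
        full = roc_auc(scores, labels)
        sub = subgroup_evaluate(scores, labels, np.ones(40, bool))
        assert sub.auc == full.auc
        assert (sub.ci_low, sub.ci_high) == (full.ci_low, full.ci_high)

    def test_empty_subgroup_errors(self):
        scores, labels = self._scored()
        with pytest.raises(ValueError, match="empty"):
            subgroup_evaluate(scores, labels, np.zeros(40, bool))

    def test_single_class_subgroup_errors(self):
        scores, labels = self._scored()
        with pytest.raises(ValueError, match="both classes"):
            subgroup_evaluate(scores, labels, (labels == 1).to_numpy())


# ---------------------------------------------------------------------------
# Logistic regression


def _ann(y):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(y))],
        "ln_status": np.where(np.asarray(y) == 1, "positive", "negative"),
    })


def _frame(x, gene="G"):
    return pd.DataFrame({gene: np.asarray(x, float)},
                        index=[f"S{i}" for i in range(len(x))])


class TestLogistic:
    def test_mirror_symmetric_data_gives_or_one(self):
        # Groups are mirror images around 0: the optimum has slope 0.
        x = [-2, -1, 1, 2, -2, -1, 1, 2]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        row = univariate_or(_frame(x), _ann(y), "G")
        assert row["odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_or_invariant_to_predictor_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(6, 1, 80)
        y = rng.binomial(1, 1 / (1 + np.exp(-(x - 6))))
        y[:2] = [0, 1]
        a = univariate_or(_frame(x), _ann(y), "G")
        b = univariate_or(_frame(x + 100.0), _ann(y), "G")
        assert a["odds_ratio"] == pytest.approx(b["odds_ratio"], abs=1e-6)

    def test_scaling_predictor_rescales_coefficient(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 120)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        y[:2] = [0, 1]
        a = univariate_or(_frame(x), _ann(y), "G")
        b = univariate_or(_frame(3.0 * x), _ann(y), "G")
        assert np.log(b["odds_ratio"]) == pytest.approx(
            np.log(a["odds_ratio"]) / 3.0, abs=1e-8)

    def test_complete_separation_flagged_not_crashed(self):
        x = [1, 2, 3, 4, 10, 11, 12, 13]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        row = univariate_or(_frame(x), _ann(y), "G")
        assert row["note"] == "possible complete separation"
        assert row["ci_high"] == np.inf

    def test_constant_predictor_gives_error_row(self):
        row = univariate_or(_frame([5.0] * 10), _ann([1, 0] * 5), "G")
        assert row["note"] == "constant predictor"
        assert np.isnan(row["odds_ratio"])

    def test_duplicated_predictor_warns_and_matches_univariate_auc(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 100)
        y = rng.binomial(1, 1 / (1 + np.exp(-1.5 * x)))
        y[:2] = [0, 1]
        df = pd.DataFrame({"G1": x, "G2": x},
                          index=[f"S{i}" for i in range(100)])
        uni = univariate_or(df, _ann(y), "G1")
        with pytest.warns(UserWarning, match="collinear"):
            roc, _ = multivariate_model(df, _ann(y), ["G1", "G2"])
        uni_auc = roc_auc(x, y).auc
        assert roc.auc == pytest.approx(uni_auc, abs=1e-9)
        assert np.isfinite(uni["odds_ratio"])

    def test_informative_pair_beats_single_genes_on_average(self):
        rng = np.random.default_rng(7)
        gains = []
        for _ in range(20):
            x1 = rng.normal(0, 1, 150)
            x2 = rng.normal(0, 1, 150)
            y = rng.binomial(1, 1 / (1 + np.exp(-(x1 + x2))))
            y[:2] = [0, 1]
            df = pd.DataFrame({"G1": x1, "G2": x2},
                              index=[f"S{i}" for i in range(150)])
            roc, _ = multivariate_model(df, _ann(y), ["G1", "G2"])
            best_single = max(roc_auc(x1, y).auc, roc_auc(x2, y).auc)
            gains.append(roc.auc - best_single)
        assert np.mean(gains) > 0


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestTwoGroupTest:
    def test_fully_separated_groups(self):
        u, p = two_group_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0  # U convention: reported for the first group
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = two_group_test([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        _, p2 = two_group_test([1.0, 2.0], [1.0, 2.0])
        assert p2 == 1.0

    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for m in range(1, 5):
            for n in range(1, 5):
                x = rng.normal(size=m)
                y = rng.normal(size=n)
                u, p = two_group_test(x, y)
                u_ref, p_ref = mwu_exact_enumeration(x, y)
                assert u == pytest.approx(u_ref)
                assert p == pytest.approx(p_ref, abs=1e-12)

    def test_tie_corrected_asymptotic_for_large_or_tied_input(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 4, 40).astype(float)
        y = rng.integers(0, 4, 40).astype(float) + 0.5
        u, p = two_group_test(x, y)
        assert 0 <= p <= 1

    def test_null_p_values_are_uniform_and_null_auc_centred(self):
        # Calibration: zero-effect groups give uniform p (KS) and AUC ~ 0.5.
        rng = np.random.default_rng(12)
        ps = []
        aucs = []
        for _ in range(1000):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            ps.append(two_group_test(x, y)[1])
        from scipy.stats import kstest
        d = kstest(ps, "uniform").statistic
        assert d < 0.05
        for _ in range(500):
            s = rng.normal(size=40)
            lab = np.r_[np.ones(20), np.zeros(20)]
            aucs.append(roc_auc(s, lab).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02


# ---------------------------------------------------------------------------
# Correlation / clustering


class TestCorrelationCluster:
    def _matrix(self, n=30, seed=1):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        return pd.DataFrame({
            "A": base + rng.normal(0, 0.3, n),
            "B": base + rng.normal(0, 0.3, n),
            "C": rng.normal(size=n),
            "D": -base + rng.normal(0, 0.3, n),
        })

    def test_duplicated_gene_merges_at_height_zero(self):
        df = self._matrix()
        df["A2"] = df["A"]
        res = correlation_cluster(df)
        assert res.corr.loc["A", "A2"] == pytest.approx(1.0)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.clusters["A"] == res.clusters["A2"]

    def test_anticorrelated_pair_sits_at_distance_two(self):
        n = 20
        x = np.linspace(0, 1, n)
        df = pd.DataFrame({"A": x, "B": -x})
        res = correlation_cluster(df)
        assert res.corr.loc["A", "B"] == pytest.approx(-1.0)
        assert res.linkage[-1, 2] == pytest.approx(2.0)

    def test_merge_heights_match_bruteforce_linkage(self):
        df = self._matrix()
        res = correlation_cluster(df)
        dist = 1.0 - df.corr().to_numpy()
        np.fill_diagonal(dist, 0.0)
        ref = complete_linkage_bruteforce(dist)
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), sorted(ref),
                                   atol=1e-12)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()

    def test_invariance_to_positive_affine_rescaling(self):
        df = self._matrix()
        scaled = df * np.array([2.0, 0.5, 3.0, 10.0]) + np.array(
            [1.0, -4.0, 0.0, 7.0])
        r0 = correlation_cluster(df)
        r1 = correlation_cluster(scaled)
        np.testing.assert_allclose(r1.corr.to_numpy(), r0.corr.to_numpy(),
                                   atol=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        df = self._matrix()
        df["K"] = 3.14
        with pytest.warns(UserWarning, match="K"):
            res = correlation_cluster(df)
        assert "K" in res.dropped
        assert "K" not in res.clusters.index
        assert res.corr.drop(index="K").drop(columns="K").notna().all().all()

    def test_symmetry_and_unit_diagonal(self):
        res = correlation_cluster(self._matrix())
        c = res.corr.to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        assert (np.abs(c) <= 1 + 1e-12).all()


# ---------------------------------------------------------------------------
# Cohort comparisons


def _cohort(counts):
    """Build an annotation frame from {level: (n_neg, n_pos)} counts."""
    rows = []
    for level, (n_neg, n_pos) in counts.items():
        rows += [{"ln_status": "negative", "cov": level}] * n_neg
        rows += [{"ln_status": "positive", "cov": level}] * n_pos
    df = pd.DataFrame(rows)
    df["sample_id"] = [f"S{i}" for i in range(len(df))]
    return df


class TestCohortCompare:
    def test_identical_proportions_give_p_one(self):
        row = cohort_compare(_cohort({"Yes": (10, 5), "No": (20, 10)}), "cov")
        assert row.test_name == "fisher"
        assert row.p_value == pytest.approx(1.0)

    def test_unknown_shown_but_excluded_from_test(self):
        row = cohort_compare(
            _cohort({"Yes": (10, 5), "No": (20, 10), "Unknown": (30, 15)}),
            "cov")
        assert "Unknown" in row.table.index
        # percentages computed over full group size including Unknown
        assert row.table.loc["Yes", "pct_negative"] == round_half_away(
            100 * 10 / 60)
        assert row.p_value == pytest.approx(1.0)

    def test_multilevel_covariate_uses_chi_square(self):
        row = cohort_compare(
            _cohort({"G1": (10, 2), "G2": (30, 20), "G3": (5, 10)}), "cov")
        assert row.test_name == "chi-square"
        assert 0 <= row.p_value <= 1

    def test_continuous_covariate_uses_mann_whitney(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(60)],
            "ln_status": ["negative"] * 30 + ["positive"] * 30,
            "age": np.r_[rng.normal(65, 8, 30), rng.normal(60, 8, 30)],
        })
        row = cohort_compare(df, "age")
        assert row.kind == "continuous"
        assert row.test_name == "mann-whitney"
        assert row.table.loc["negative", "n"] == 30

    def test_entirely_unknown_covariate_gets_no_test(self):
        row = cohort_compare(_cohort({"Unknown": (10, 5)}), "cov")
        assert row.test_name == "none"
        assert np.isnan(row.p_value)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(37.5) == 38
        assert round_half_away(12.5) == 13
        assert round_half_away(13.19) == 13
        assert round_half_away(-2.5) == -3
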