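"""Percentile thresholds, 2-of-3 rule, severity/extremes, PCA, χ²."""

import numpy as np
import pandas as pd
import pytest

from addictomir import (classify_cohort, criterion_thresholds, group_chi2,
                        pca_profile, severity_and_extremes, severity_scores)
from addictomir.classify import CRITERIA


def scores_frame(persistence, breaking_point=None, shocks=None, ids=None):
    persistence = np.asarray(persistence, dtype=float)
    n = len(persistence)
    return pd.DataFrame({
        "mouse_id": ids or [f"m{i:03d}" for i in range(n)],
        "persistence": persistence,
        "breaking_point": (persistence if breaking_point is None
                           else np.asarray(breaking_point, float)),
        "shocks": persistence if shocks is None else np.asarray(shocks, float),
    })


class TestThresholds:
    def test_linear_interpolation_matches_numpy(self):
        df = scores_frame(range(1, 9))
        thr = criterion_thresholds(df, 0.75)
        assert thr["persistence"] == pytest.approx(6.25)
        # independent implementation of the same convention
        assert thr["persistence"] == pytest.approx(
            np.percentile(np.arange(1, 9), 75, method="linear"))

    def test_equal_scores_make_nobody_positive(self):
        df = scores_frame([5.0] * 10)
        thr = criterion_thresholds(df)
        res = classify_cohort(df, thr)
        assert (res["n_criteria"] == 0).all()

    def test_q_zero_threshold_is_minimum(self):
        df = scores_frame([3, 1, 4, 1, 5])
        thr = criterion_thresholds(df, q=0.0)
        assert thr["persistence"] == 1
        res = classify_cohort(df, thr)
        assert (res["persistence_positive"] == (df["persistence"] > 1)).all()

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            criterion_thresholds(scores_frame([1, 2, 3]))

    def test_monotone_transform_leaves_classification_unchanged(self):
        rng = np.random.default_rng(5)
        df = scores_frame(rng.normal(size=30), rng.normal(size=30),
                          rng.normal(size=30))
        res1 = classify_cohort(df, criterion_thresholds(df))
        df2 = df.copy()
        for c in CRITERIA:
            df2[c] = np.exp(df2[c])  # strictly monotone
        res2 = classify_cohort(df2, criterion_thresholds(df2))
        assert (res1["label"] == res2["label"]).all()


class TestTwoOfThreeRule:
    def test_two_positive_criteria_mean_addicted(self):
        df = scores_frame([10, 0, 0, 0, 0],      # positive
                          [10, 0, 0, 0, 0],      # positive
                          [0, 10, 0, 0, 0])      # not for mouse 0
        res = classify_cohort(df, criterion_thresholds(df))
        m0 = res.iloc[0]
        assert bool(m0["persistence_positive"]) and bool(m0["breaking_point_positive"])
        assert not m0["shocks_positive"]
        assert m0["label"] == "addicted"

    def test_no_positive_criteria_mean_nonaddicted(self):
        df = scores_frame([0, 0, 0, 0, 10])
        res = classify_cohort(df, criterion_thresholds(df))
        assert res.iloc[0]["label"] == "nonaddicted"

    def test_missing_criterion_excludes_mouse(self):
        df = scores_frame([1, 2, 3, 4, 5])
        thr = criterion_thresholds(df)
        df.loc[2, "shocks"] = np.nan
        res = classify_cohort(df, thr)
        assert len(res) == 4
        assert "m002" not in set(res["mouse_id"])


class TestSeverityAndExtremes:
    def test_dominant_mouse_is_discovery_vulnerable(self):
        rng = np.random.default_rng(0)
        df = scores_frame(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30),
                          rng.uniform(0, 1, 30))
        df.loc[0, CRITERIA] = [10.0, 10.0, 10.0]  # dominates everything
        res = severity_and_extremes(
            classify_cohort(df, criterion_thresholds(df)), k=2)
        top = res.loc[res["severity"].idxmax()]
        assert top["mouse_id"] == "m000"
        assert top["extreme_set"] == "discovery"
        assert top["extreme_side"] == "vulnerable"

    def test_median_mouse_has_severity_half(self):
        df = scores_frame(range(1, 12))
        res = classify_cohort(df, criterion_thresholds(df))
        sev = severity_scores(res)
        assert sev.iloc[5] == pytest.approx(0.5)

    def test_severity_invariant_to_row_permutation(self):
        rng = np.random.default_rng(3)
        df = scores_frame(rng.normal(size=20), rng.normal(size=20),
                          rng.normal(size=20))
        res = classify_cohort(df, criterion_thresholds(df))
        sev = severity_scores(res)
        perm = rng.permutation(20)
        sev_p = severity_scores(res.iloc[perm].reset_index(drop=True))
        assert np.allclose(sev.to_numpy()[perm], sev_p.to_numpy())

    def test_discovery_and_replica_never_overlap(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = scores_frame(rng.normal(size=40), rng.normal(size=40),
                              rng.normal(size=40))
            res = severity_and_extremes(
                classify_cohort(df, criterion_thresholds(df)), k=3)
            for side in ("vulnerable", "resilient"):
                disc = set(res.loc[(res.extreme_set == "discovery")
                                   & (res.extreme_side == side), "mouse_id"])
                repl = set(res.loc[(res.extreme_set == "replica")
                                   & (res.extreme_side == side), "mouse_id"])
                assert not disc & repl
                assert len(disc | repl) <= 6


class TestPCA:
    def test_identical_features_load_together(self):
        rng = np.random.default_rng(1)
        n = 60
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "persistence": base, "breaking_point": base,
            "shocks": rng.normal(size=n), "impulsivity": rng.normal(size=n),
            "flexibility_errors": rng.normal(size=n),
            "appetitive_reactivity": rng.normal(size=n),
            "aversive_reactivity": rng.normal(size=n),
        })
        prof = pca_profile(df)
        pc1 = prof.loadings["PC1"]
        assert np.sign(pc1["persistence"]) == np.sign(pc1["breaking_point"])
        assert abs(pc1["persistence"]) > 0.5 and abs(pc1["breaking_point"]) > 0.5

    def test_variance_explained_sums_to_100(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 7)),
                          columns=["persistence", "breaking_point", "shocks",
                                   "impulsivity", "flexibility_errors",
                                   "appetitive_reactivity",
                                   "aversive_reactivity"])
        prof = pca_profile(df)
        assert prof.variance_explained.sum() == pytest.approx(100.0)
        assert (np.diff(prof.variance_explained) <= 1e-9).all()
        # unit-norm loading columns
        assert np.allclose((prof.loadings ** 2).sum(axis=0), 1.0)

    def test_sign_flip_flips_only_that_loading(self):
        rng = np.random.default_rng(4)
        cols = ["persistence", "breaking_point", "shocks", "impulsivity",
                "flexibility_errors", "appetitive_reactivity",
                "aversive_reactivity"]
        df = pd.DataFrame(rng.normal(size=(40, 7)), columns=cols)
        p1 = pca_profile(df)
        df2 = df.copy()
        df2["shocks"] = -df2["shocks"]
        p2 = pca_profile(df2)
        assert np.allclose(p1.variance_explained, p2.variance_explained)
        assert np.allclose(np.abs(p1.loadings.loc["shocks"]),
                           np.abs(p2.loadings.loc["shocks"]))


def chi2_textbook(table):
    """Independent textbook formula: sum (O - E)^2 / E."""
    t = np.asarray(table, float)
    row = t.sum(1, keepdims=True)
    col = t.sum(0, keepdims=True)
    e = row @ col / t.sum()
    return float(((t - e) ** 2 / e).sum())


class TestGroupChi2:
    def test_published_arm_counts_match_formula_oracle(self):
        # 6/12 vs 3/19 addicted (the 50.0% vs 15.8% comparison)
        table = [[6, 6], [3, 16]]
        chi2, p = group_chi2(table)
        assert chi2 == pytest.approx(chi2_textbook(table))
        assert 0 < p < 1

    def test_identical_proportions_give_zero(self):
        chi2, p = group_chi2([[5, 5], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        a, _ = group_chi2([[6, 6], [3, 16]])
        b, _ = group_chi2([[3, 16], [6, 6]])
        assert a == pytest.approx(b)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            group_chi2([[0, 0], [3, 16]])
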