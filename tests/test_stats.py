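"""Normality, omnibus rank test, post-hoc z tests, and boxplot summaries."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from pavis.stats import (
    boxplot_summary,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    shapiro_wilk,
    significance_stars,
)


def brute_force_kruskal_h(groups):
    """Hand formula on pooled ranks, including tie correction."""
    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    n = pooled.size
    start, num = 0, 0.0
    for v in groups.values():
        r = ranks[start : start + len(v)]
        num += len(v) * (r.mean() - (n + 1) / 2) ** 2
        start += len(v)
    h = 12.0 / (n * (n + 1)) * num
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestShapiroWilk:
    def test_calibration_on_normal_draws(self):
        ok = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=500))[1] > 0.05
            for s in range(100)
        )
        assert ok >= 90

    def test_power_on_exponential_draws(self):
        rejected = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=500))[1] < 0.05
            for s in range(100)
        )
        assert rejected >= 95

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="constant sample"):
            shapiro_wilk([2.0] * 10)

    def test_out_of_range_n_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestKruskalWallis:
    def test_hand_computed_h_no_ties(self):
        h, _ = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(3.857, abs=1e-3)
        assert h == pytest.approx(brute_force_kruskal_h({"a": [1, 2, 3], "b": [4, 5, 6]}))

    def test_identical_groups_h_zero_p_one(self):
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_with_ties(self, rng):
        groups = {i: rng.integers(0, 5, rng.integers(5, 15)).astype(float) for i in range(3)}
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(brute_force_kruskal_h(groups), abs=1e-9)

    def test_degenerate_all_identical_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [5, 5, 5], "b": [5, 5, 5]})

    def test_invariant_under_monotone_transform(self, rng):
        groups = {i: rng.normal(i, 1, 20) for i in range(3)}
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis({k: np.exp(v) for k, v in groups.items()})
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_two_group_p_close_to_mann_whitney(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 25)
        _, p_kw = kruskal_wallis({"a": a, "b": b})
        p_mw = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert p_kw == pytest.approx(p_mw, rel=0.10)


class TestDunnPosthoc:
    def test_identical_groups_z_zero(self):
        res = dunn_posthoc({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert res[0]["z"] == pytest.approx(0.0, abs=1e-12)
        assert res[0]["p"] == pytest.approx(1.0)

    def test_hand_computed_mean_rank_difference(self):
        groups = {"a": [1.0, 2, 3], "b": [10.0, 11, 12]}
        res = dunn_posthoc(groups)[0]
        n = 6
        var = n * (n + 1) / 12.0  # no ties
        expected = (2.0 - 5.0) / np.sqrt(var * (1 / 3 + 1 / 3))
        assert res["z"] == pytest.approx(expected, abs=1e-12)

    def test_relabeling_flips_sign_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        r1 = dunn_posthoc({"a": a, "b": b})[0]
        r2 = dunn_posthoc({"a": b, "b": a})[0]
        assert r1["z"] == pytest.approx(-r2["z"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_bonferroni_scales_p(self, rng):
        groups = {i: rng.normal(i * 0.3, 1, 10) for i in range(3)}
        raw = dunn_posthoc(groups, adjust="none")
        adj = dunn_posthoc(groups, adjust="bonferroni")
        for r, a in zip(raw, adj):
            assert a["p"] == pytest.approx(min(1.0, r["p"] * 3))

    def test_omnibus_power_with_unbalanced_groups(self):
        """Six groups at the retained-frame sample sizes with one location
        shifted by one pooled SD: the omnibus test rejects >90% of runs."""
        sizes = (28, 43, 39, 64, 48, 65)
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            g = np.random.default_rng(s)
            groups = {i: g.normal(0, 1, n) for i, n in enumerate(sizes)}
            groups[1] = groups[1] + 1.0
            _, p = kruskal_wallis(groups)
            hits += p < 0.05
        assert hits / n_rep > 0.9


class TestBoxplotSummary:
    def test_hand_computed_with_outlier(self):
        s = boxplot_summary([1, 2, 3, 4, 100])
        assert s["median"] == 3
        assert s["q1"] == 2 and s["q3"] == 4
        assert s["outliers"] == [100]
        assert s["whisker_high"] == 4

    def test_constant_sample(self):
        s = boxplot_summary([7.0] * 5)
        assert s["median"] == 7.0
        assert s["q1"] == s["q3"] == 7.0
        assert s["outliers"] == []

    def test_symmetric_sample_quartiles(self):
        s = boxplot_summary([-2, -1, 0, 1, 2])
        assert s["median"] - s["q1"] == pytest.approx(s["q3"] - s["median"])

    def test_whiskers_within_fences(self, rng):
        x = rng.normal(size=200)
        s = boxplot_summary(x)
        iqr = s["q3"] - s["q1"]
        assert s["whisker_low"] >= s["q1"] - 1.5 * iqr
        assert s["whisker_high"] <= s["q3"] + 1.5 * iqr


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.5, "ns"),
            (0.05, "ns"),
            (0.03, "*"),
            (0.009, "**"),
            (0.0009, "***"),
            (0.00005, "****"),
            (0.0, "****"),
        ],
    )
    def test_thresholds_strict(self, p, label):
        assert significance_stars(p) == label

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestCompareGroups:
    def test_full_report_structure(self, rng):
        groups = {10.0: rng.normal(0, 1, 20), 20.0: rng.normal(1, 1, 25)}
        res = compare_groups(groups, metric="gcnr")
        d = res.to_dict()
        assert set(d["normality"]) == {10.0, 20.0}
        assert len(d["pairwise"]) == 1
        assert d["pairwise"][0]["stars"] in ("ns", "*", "**", "***", "****")
        assert d["boxplot_summaries"][10.0]["n"] == 20
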