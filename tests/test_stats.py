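"""Primitive tests, FDR, and the variability scans, against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as sps

import tractvar as tv
from tractvar.stats import DEFAULT_SCHEDULE, ComparisonSchedule

from conftest import null_config


# ---------------------------------------------------------------- oracles
def brute_force_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by explicit enumeration of all 2^n patterns."""
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    sums = []
    for signs in itertools.product((0, 1), repeat=n):
        sums.append(sum(r for s, r in zip(signs, ranks) if s))
    sums = np.asarray(sums)
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_force_bh(p: np.ndarray, q: float):
    """Step-up definition: reject 1..k where k = max{i : p_(i) <= i q / m}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    for pos, idx in enumerate(order, start=1):
        adj[idx] = min(min(m * p[o] / (j + 1) for j, o in enumerate(order) if j + 1 >= pos), 1.0)
    return adj, reject


# ---------------------------------------------------------------- wilcoxon
class TestWilcoxon:
    def test_all_ties_give_p_one(self):
        res = tv.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_raw == 1.0 and res.degenerate

    def test_five_positive_pairs(self):
        # all 5 differences positive: exact two-sided p = 2/2^5
        res = tv.wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.p_raw == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        left = rng.normal(size=n)
        right = rng.normal(size=n)
        res = tv.wilcoxon_signed_rank(left, right)
        assert res.p_raw == pytest.approx(brute_force_wilcoxon_p(left - right))

    def test_exact_with_tied_ranks_matches_enumeration(self):
        left = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 8.0])
        right = np.array([1.0, 3.0, 2.0, 4.0, 5.0, 7.0])  # |d| ties
        res = tv.wilcoxon_signed_rank(left, right)
        assert res.p_raw == pytest.approx(brute_force_wilcoxon_p(left - right))

    def test_zero_differences_dropped(self):
        res = tv.wilcoxon_signed_rank([1, 2, 5, 7], [1, 2, 3, 4])
        ref = tv.wilcoxon_signed_rank([5, 7], [3, 4])
        assert res.p_raw == ref.p_raw

    def test_large_sample_approximation_tracks_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 60)
        res = tv.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=True, mode="approx")
        assert res.p_raw == pytest.approx(ref.pvalue, rel=0.02)


# ---------------------------------------------------------------- t / F
class TestTwoSampleT:
    def test_identical_samples(self):
        res = tv.two_sample_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_p_decreases_with_shift(self):
        a = np.array([1.0, 2.0, 3.0])
        ps = [tv.two_sample_t(a, a + d).p_raw for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_pooled_formula_oracle(self):
        a = np.array([4.1, 5.2, 6.3, 5.8])
        b = np.array([3.9, 4.0, 5.1])
        res = tv.two_sample_t(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
        assert res.statistic == pytest.approx(t)
        assert res.p_raw == pytest.approx(p)

    def test_degenerate_zero_variance(self):
        res = tv.two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res.p_raw == 0.0 and res.degenerate

    def test_welch_flag(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 3, 15)
        res = tv.two_sample_t(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.p_raw == pytest.approx(ref.pvalue)


class TestTwoSampleF:
    def test_equal_variances(self):
        a = [1.0, 2.0, 3.0]
        res = tv.two_sample_f(a, [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(size=15)
        r1 = tv.two_sample_f(a, b)
        r2 = tv.two_sample_f(3.7 * a, 3.7 * b)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_distribution_function_oracle(self):
        # variance ratio 4 with n = 11 per group: p from F(10, 10)
        a = np.sqrt(4.0) * np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, -1.5, 2.0, -2.0, 0.25, -0.25])
        b = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5, -1.5, 2.0, -2.0, 0.25, -0.25])
        res = tv.two_sample_f(a, b)
        assert res.statistic == pytest.approx(4.0)
        expected = 2 * min(sps.f(10, 10).cdf(4.0), sps.f(10, 10).sf(4.0))
        assert res.p_raw == pytest.approx(expected)

    def test_zero_variance_degenerate(self):
        res = tv.two_sample_f([1.0, 1.0], [1.0, 2.0])
        assert res.degenerate


# ---------------------------------------------------------------- BH-FDR
class TestBHFDR:
    def test_single_p(self):
        adj, rej = tv.bh_fdr([0.04], 0.05)
        assert adj[0] == pytest.approx(0.04) and rej[0]

    def test_equally_spaced_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        adj, rej = tv.bh_fdr(p, 0.05)
        assert rej.all()  # largest i with p_(i) <= i q/m is i = 5

    def test_all_ones_none_rejected(self):
        adj, rej = tv.bh_fdr([1.0] * 6, 0.05)
        assert not rej.any() and np.all(adj == 1.0)

    def test_empty(self):
        adj, rej = tv.bh_fdr([], 0.05)
        assert adj.size == 0 and rej.size == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 9))
        p = np.round(rng.random(m), 3)
        adj, rej = tv.bh_fdr(p, 0.05)
        adj_bf, rej_bf = brute_force_bh(p, 0.05)
        np.testing.assert_allclose(adj, adj_bf)
        np.testing.assert_array_equal(rej, rej_bf)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.random(40)
        adj, rej = tv.bh_fdr(p, 0.05)
        rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, adj_sm)
        np.testing.assert_array_equal(rej, rej_sm)


# ---------------------------------------------------------------- summaries
class TestChangeSummaries:
    def test_percent_change(self):
        assert tv.percent_change(0.4, 0.5) == pytest.approx(25.0)
        assert tv.percent_change(3.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            tv.percent_change(0.0, 1.0)

    def test_log_variance_ratio_halving_and_doubling(self):
        assert round(tv.log_variance_ratio(1.0, 0.5), 2) == -0.69
        assert round(tv.log_variance_ratio(1.0, 2.0), 2) == 0.69
        assert tv.log_variance_ratio(3.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            tv.log_variance_ratio(0.0, 1.0)


# ---------------------------------------------------------------- schedule
def test_default_schedule_pairs():
    assert len(DEFAULT_SCHEDULE.pairs) == 4
    cohort_of = {e.name: e.cohort for e in tv.DEFAULT_EPOCHS}
    for early, late in DEFAULT_SCHEDULE.pairs:
        assert cohort_of[early] == cohort_of[late]


def test_cross_protocol_schedule_rejected():
    with pytest.raises(ValueError, match="protocol"):
        ComparisonSchedule(
            pairs=(("late_infancy", "childhood"),), labels=("bad",)
        )


# ---------------------------------------------------------------- scans
class TestAsymmetryScan:
    def test_planted_offset_detected(self, registry):
        cfg = null_config(n_per_epoch=25, seed=13,
                          asymmetry_offsets={("AF", "FA"): 0.02})
        subjects = tv.make_cohort(cfg)
        table, _ = tv.make_feature_table(subjects, registry, cfg, features=["FA"])
        res = tv.asymmetry_scan(table, "FA", registry=registry)
        assert len(res) == 28
        af = res[res["pathway"] == "AF"].iloc[0]
        assert af["significant"]
        assert af["mean_diff"] > 0

    def test_missing_feature_rejected(self, medium_tables):
        _, table, _, _ = medium_tables
        with pytest.raises(ValueError, match="absent"):
            tv.asymmetry_scan(table, "nonexistent")

    def test_fdr_adjusted_geq_raw(self, medium_tables):
        _, table, _, _ = medium_tables
        res = tv.asymmetry_scan(table, "volume")
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()


class TestLifespanScan:
    def test_variance_convergence_divergence_signs(self, registry_by_name):
        cfg = tv.SyntheticConfig(n_per_epoch=100, seed=14)
        subjects = tv.make_cohort(cfg)
        reg = [registry_by_name["CC_2"], registry_by_name["CC_5"]]
        table, _ = tv.make_feature_table(subjects, reg, cfg, features=["FA"])
        res = tv.lifespan_scan(table, "FA")
        expected_sign = {"infancy": -1, "development": -1,
                         "middle_adulthood": 1, "late_adulthood": 1}
        for _, row in res.iterrows():
            assert np.sign(row["log_variance_ratio"]) == expected_sign[row["pair"]]

    def test_variance_halving_in_infancy_recovered(self, registry_by_name):
        # variance halves from the first to the second epoch: log ratio
        # ~ -0.69 and the F test flags it at n = 200 per epoch
        profile = (1.0, math.sqrt(0.5), 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        cfg = null_config(n_per_epoch=200, seed=17, variance_profile=profile)
        subjects = [s for s in tv.make_cohort(cfg) if s.cohort == "Infant"]
        reg = [registry_by_name["CC_2"]]
        table, _ = tv.make_feature_table(subjects, reg, cfg, features=["FA"])
        res = tv.lifespan_scan(table, "FA")
        row = res[res["pair"] == "infancy"].iloc[0]
        assert row["log_variance_ratio"] == pytest.approx(-0.69, abs=0.35)
        assert row["significant_var"]

    def test_pairs_follow_schedule(self, medium_tables):
        _, table, _, _ = medium_tables
        res = tv.lifespan_scan(table, "MD")
        assert set(res["pair"]) == set(DEFAULT_SCHEDULE.labels)
        assert set(zip(res["epoch_early"], res["epoch_late"])) == set(
            DEFAULT_SCHEDULE.pairs
        )

    def test_unpopulated_epoch_skipped(self, registry_by_name):
        cfg = tv.SyntheticConfig(n_per_epoch=5, seed=15)
        subjects = [s for s in tv.make_cohort(cfg) if s.epoch != "early_infancy"]
        reg = [registry_by_name["CC_1"]]
        table, _ = tv.make_feature_table(subjects, reg, cfg, features=["FA"])
        res = tv.lifespan_scan(table, "FA")
        assert "infancy" not in set(res["pair"])


class TestVarianceAsymmetryScan:
    def test_planted_left_variance_excess_detected(self, registry):
        cfg = null_config(n_per_epoch=50, seed=16,
                          left_variance_multipliers={("AF", "volume"): 4.0})
        subjects = [s for s in tv.make_cohort(cfg) if s.epoch == "young_adulthood"]
        subjects = subjects * 4  # 200 subjects in the epoch
        subjects = [
            tv.SubjectRecord(f"s{i}", s.age, s.sex, s.cohort, s.epoch)
            for i, s in enumerate(subjects)
        ]
        table, _ = tv.make_feature_table(subjects, registry, cfg, features=["volume"])
        res = tv.variance_asymmetry_scan(table, "volume", "young_adulthood")
        af = res[res["pathway"] == "AF"].iloc[0]
        assert af["significant"] and af["var_ratio_lr"] > 1

    def test_identical_hemispheres_f_one(self, registry_by_name):
        rows = []
        for i in range(10):
            rows.append({"subject_id": f"s{i}", "pathway": "AF_left",
                         "feature": "volume", "value": float(i), "epoch": "young_adulthood"})
            rows.append({"subject_id": f"s{i}", "pathway": "AF_right",
                         "feature": "volume", "value": float(i), "epoch": "young_adulthood"})
        table = pd.DataFrame(rows)
        res = tv.variance_asymmetry_scan(table, "volume", "young_adulthood")
        af = res[res["pathway"] == "AF"].iloc[0]
        assert af["statistic"] == pytest.approx(1.0)
        assert af["p_raw"] == pytest.approx(1.0)


class TestPopulationSD:
    def test_matches_two_pass_oracle_and_order(self, medium_tables):
        _, table, _, _ = medium_tables
        res = tv.population_sd_profile(table, "FA", "young_adulthood")
        assert len(res) == 64
        # ordered by category then ap_rank
        cats = list(res["category"])
        order = {c: i for i, c in enumerate(dict.fromkeys(cats))}
        assert cats == sorted(cats, key=order.get)
        sub = table[(table["feature"] == "FA") & (table["epoch"] == "young_adulthood")]
        for _, row in res.sample(5, random_state=0).iterrows():
            vals = sub.loc[sub["pathway"] == row["pathway"], "value"].to_numpy()
            mean = vals.sum() / len(vals)
            two_pass = math.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
            assert row["sd"] == pytest.approx(two_pass)

    def test_undefined_for_single_subject(self, registry_by_name):
        table = pd.DataFrame(
            [{"subject_id": "s0", "pathway": "CC_1", "feature": "FA",
              "value": 0.5, "epoch": "childhood"}]
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            tv.population_sd_profile(table, "FA", "childhood",
                                     registry=[registry_by_name["CC_1"]])
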