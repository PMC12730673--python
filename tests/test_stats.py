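"""Group statistics: ANOVA routes, gates, effect sizes, LMM, odor k-means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

import msdual as md
from msdual.stats import GroupSummary, _dunn_bonferroni
from msdual import simulate as sim

CRS_R = [("HC", 9, 22.8, 0.1), ("MCS+", 6, 17.8, 1.17),
         ("MCS-", 6, 10.3, 1.03), ("VS", 6, 6.2, 1.72)]


def _summaries(rows):
    return [GroupSummary(*r) for r in rows]


class TestAnovaFromSummary:
    def test_crsr_table_reproduced(self):
        res = md.anova_from_summary(_summaries(CRS_R))
        assert res.statistic == pytest.approx(337.76, abs=0.01)
        assert res.df == (3, 23)
        assert res.effect == pytest.approx(0.97, abs=0.01)
        assert res.p < 0.001

    def test_equal_means_zero_f(self):
        rows = [("a", 5, 3.0, 1.0), ("b", 5, 3.0, 2.0)]
        res = md.anova_from_summary(_summaries(rows))
        assert res.statistic == 0.0 and res.effect == 0.0

    def test_two_groups_f_equals_t_squared(self):
        rows = [("a", 8, 5.0, 1.2), ("b", 10, 6.1, 1.4)]
        xs = {r[0]: sim.summary_matched_sample(r[2], r[3], r[1], seed=i)
              for i, r in enumerate(rows)}
        t = sstats.ttest_ind(xs["a"], xs["b"]).statistic
        res = md.anova_from_summary(_summaries(rows))
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary("a", 5, 0.0, -1.0)


class TestAnovaEquivalence:
    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_summary_equals_raw_on_matched_samples(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"g{i}", int(rng.integers(3, 12)),
                 float(rng.normal(0, 5)), float(rng.uniform(0.5, 3)))
                for i in range(int(rng.integers(2, 5)))]
        samples = {r[0]: sim.summary_matched_sample(r[2], r[3], r[1], seed + i)
                   for i, r in enumerate(rows)}
        a = md.anova_from_summary(_summaries(rows))
        b = md.anova_oneway(samples)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-8)
        assert a.effect == pytest.approx(b.effect, abs=1e-8)
        assert a.p == pytest.approx(b.p, abs=1e-8)

    def test_group_order_irrelevant(self, rng):
        samples = {k: rng.normal(size=6) for k in "abc"}
        f1 = md.anova_oneway(samples).statistic
        f2 = md.anova_oneway(dict(reversed(samples.items()))).statistic
        assert f1 == pytest.approx(f2)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            md.anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


class TestAssumptionGate:
    def test_normal_data_routes_parametric(self):
        # five independent gates at alpha=0.05 pass jointly with
        # probability ~0.95^5 ~ 0.77; over 40 seeds expect ~31 +/- 2.7
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            samples = {k: rng.normal(size=30) for k in "abcd"}
            hits += md.assumption_gate(samples) == "parametric"
        assert hits >= 23

    def test_two_point_distribution_routes_nonparametric(self, rng):
        samples = {"a": rng.normal(size=30),
                   "b": rng.choice([0.0, 10.0], size=30)}
        assert md.assumption_gate(samples) == "nonparametric"

    def test_constant_groups_route_nonparametric(self):
        samples = {"a": np.ones(10), "b": np.ones(10)}
        assert md.assumption_gate(samples) == "nonparametric"


class TestKruskalWallis:
    def test_all_identical_h_zero(self):
        res = md.kruskal_wallis({"a": np.ones(5), "b": np.ones(5)})
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_computed_h(self):
        # three groups, non-overlapping ranges, n=5 each, no ties:
        # ranks 1-5, 6-10, 11-15 -> H = 12/(N(N+1)) * sum n (Rbar - (N+1)/2)^2
        samples = {"lo": np.arange(1.0, 6), "mid": np.arange(11.0, 16),
                   "hi": np.arange(21.0, 26)}
        N = 15
        h_hand = 12.0 / (N * (N + 1)) * (5 * (3 - 8) ** 2 + 5 * (8 - 8) ** 2
                                         + 5 * (13 - 8) ** 2)
        res = md.kruskal_wallis(samples)
        assert res.statistic == pytest.approx(h_hand)
        assert res.effect == pytest.approx(h_hand * (N + 1) / (N**2 - 1))

    def test_epsilon_squared_in_range(self, rng):
        for _ in range(10):
            samples = {k: rng.normal(size=8) for k in "abc"}
            res = md.kruskal_wallis(samples)
            assert 0.0 <= res.effect <= 1.0

    def test_significant_result_attaches_dunn_posthoc(self):
        samples = {"lo": np.arange(1.0, 7), "hi": np.arange(21.0, 27),
                   "mid": np.arange(11.0, 17)}
        res = md.kruskal_wallis(samples)
        assert res.p < 0.05
        assert res.posthoc is not None and len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()


class TestBonferroni:
    def test_four_groups_six_pairs(self, rng):
        samples = {k: rng.normal(size=6) for k in "abcd"}
        table = md.bonferroni_pairwise(samples, "t")
        assert len(table) == 6
        assert np.allclose(table["p_adj"],
                           np.minimum(1.0, table["p_raw"] * 6))

    def test_capping_at_one(self, rng):
        samples = {k: rng.normal(size=20) for k in "abcd"}
        table = md.bonferroni_pairwise(samples, "t")
        assert (table["p_adj"] <= 1.0).all()

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_adjustment_preserves_order(self, seed):
        rng = np.random.default_rng(seed)
        samples = {k: rng.normal(rng.normal(0, 1), 1, size=6) for k in "abcd"}
        table = md.bonferroni_pairwise(samples, "t")
        order_raw = table["p_raw"].rank()
        order_adj = table["p_adj"].rank(method="min")
        # ties after capping allowed; otherwise order preserved
        uncapped = table["p_adj"] < 1.0
        assert (table.loc[uncapped, "p_raw"].rank()
                == table.loc[uncapped, "p_adj"].rank()).all()


class TestCohensD:
    # reported pairs from the dual-template comparison tables
    @pytest.mark.parametrize("m1,s1,m2,s2,expected", [
        (4.1, 0.4, 2.4, 0.6, 3.33),
        (12.1, 3.4, 9.6, 2.9, 0.79),
        (87.1, 6.3, 74.6, 3.9, 2.38),
        (16.1, 3.2, 12.1, 2.3, 1.44),
        (7.1, 1.2, 3.8, 1.1, 2.87),
        (97.6, 10.2, 82.3, 11.9, 1.38),
        (23.5, 3.2, 14.7, 4.1, 2.4),
    ])
    def test_reported_effect_sizes(self, m1, s1, m2, s2, expected):
        d = md.cohens_d(GroupSummary("x", 6, m1, s1), GroupSummary("y", 6, m2, s2))
        assert d == pytest.approx(expected, abs=0.01)

    def test_antisymmetry_and_zero(self):
        a, b = GroupSummary("a", 5, 3.0, 1.0), GroupSummary("b", 5, 5.0, 2.0)
        assert md.cohens_d(a, b) == -md.cohens_d(b, a)
        assert md.cohens_d(a, GroupSummary("c", 5, 3.0, 2.0)) == 0.0

    def test_both_zero_sds_error(self):
        with pytest.raises(ValueError):
            md.cohens_d(GroupSummary("a", 5, 1.0, 0.0),
                        GroupSummary("b", 5, 2.0, 0.0))

    def test_weighted_variant_differs_for_unequal_n(self):
        a, b = GroupSummary("a", 20, 3.0, 1.0), GroupSummary("b", 4, 5.0, 3.0)
        assert md.cohens_d(a, b) != md.cohens_d(a, b, weighted=True)


class TestRankBiserial:
    def test_complete_separation(self):
        assert md.rank_biserial([5.0, 6, 7], [1.0, 2, 3]) == 1.0
        assert md.rank_biserial([1.0, 2, 3], [5.0, 6, 7]) == -1.0

    def test_paired_all_positive(self):
        x = np.array([3.0, 4, 5, 6])
        y = x - 1.0
        assert md.rank_biserial(x, y, paired=True) == 1.0

    def test_identical_distributions_near_zero(self, rng):
        vals = [md.rank_biserial(rng.normal(size=200), rng.normal(size=200))
                for _ in range(20)]
        assert abs(np.mean(vals)) < 0.05


class TestLmm:
    @staticmethod
    def _task_frame(rng, hc_effect=0.0, noise=1.0, n_per=(5, 5)):
        rows = []
        for g, n in zip(("HC", "VS"), n_per):
            for s in range(n):
                b = rng.normal(0, 1)
                for c in ("V", "O", "V-O"):
                    eff = hc_effect if (g == "HC" and c == "V-O") else 0.0
                    rows.append({"subject": f"{g}{s}", "group": g,
                                 "condition": c,
                                 "value": b + eff + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_type_i_error_bounded(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            md.lmm_task_model(self._task_frame(rng))["interaction"].p < 0.05
            for _ in range(50))
        assert rejections <= 5  # <= 10% of replicates

    def test_power_at_large_effect(self):
        rng = np.random.default_rng(1)
        hits = contrasts = 0
        n_rep = 20
        for _ in range(n_rep):
            res = md.lmm_task_model(self._task_frame(rng, hc_effect=5.0))
            hits += res["interaction"].p < 0.05
            row = res["contrasts"]
            row = row[(row["group"] == "HC") & (row["contrast"] == "V - V-O")]
            contrasts += float(row["p"].iloc[0]) < 0.05
        assert hits >= 0.9 * n_rep
        assert contrasts >= 0.9 * n_rep

    def test_zero_noise_recovers_cell_means(self):
        rng = np.random.default_rng(2)
        df = self._task_frame(rng, hc_effect=2.0, noise=0.0)
        # remove subject effects so cells are exact
        df["value"] = df.groupby(["group", "condition"])["value"].transform("mean")
        res = md.lmm_task_model(df)
        fe = res["fixed_effects"]["estimate"]
        cells = df.groupby(["group", "condition"])["value"].mean()
        assert fe["Intercept"] == pytest.approx(cells["HC", "O"], abs=1e-6)

    def test_non_estimable_design_raises(self):
        df = pd.DataFrame({"subject": ["s1", "s1"], "group": ["a", "a"],
                           "condition": ["V", "O"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            md.lmm_task_model(df)


class TestVadKmeans:
    def test_centroids_recovered_near_truth(self):
        ratings = sim.simulate_sam_ratings(spread=0.3, seed=2)
        _, centroids = md.vad_kmeans(ratings, k=3, seed=0)
        got = centroids.to_numpy()
        for truth in sim.SAM_CENTROIDS:
            dist = np.abs(got - truth).max(axis=1).min()
            assert dist < 0.5

    def test_k1_grand_mean(self):
        ratings = sim.simulate_sam_ratings(spread=0.5, seed=3)
        _, centroids = md.vad_kmeans(ratings, k=1, seed=0)
        assert np.allclose(centroids.to_numpy()[0],
                           ratings[["valence", "arousal", "dominance"]].mean())

    def test_k_equals_n_zero_inertia(self):
        ratings = sim.simulate_sam_ratings(spread=0.5, n_odors=6, seed=4)
        labels, centroids = md.vad_kmeans(ratings, k=6, seed=0)
        assert len(set(labels)) == 6


class TestDunn:
    def test_z_sign_matches_rank_ordering(self):
        samples = {"lo": np.arange(1.0, 7), "hi": np.arange(21.0, 27)}
        table = _dunn_bonferroni(samples)
        assert table["z"].iloc[0] < 0  # lo mean rank below hi
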