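import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapsort.clustering import ChannelModel
from mapsort.sortdef import (
    SortCluster,
    build_enrichment_table,
    enrichment,
    enumerate_conjunctions,
    max_achievable_enrichment,
    rank_and_select,
)


def _models(n_channels, k):
    rng = np.random.default_rng(0)
    return [ChannelModel(c, rng.normal(size=(k, 5))) for c in range(n_channels)]


class TestSortCluster:
    def test_duplicate_channel_rejected(self):
        with pytest.raises(ValueError):
            SortCluster(((0, 1), (0, 2)))

    def test_membership_is_intersection(self):
        assign = np.array([[0, 1], [0, 0], [1, 1], [0, 1], [2, 1]])
        sc = SortCluster(((0, 0), (1, 1)))
        np.testing.assert_array_equal(sc.membership(assign), [True, False, False, True, False])


class TestEnumerateConjunctions:
    def test_4_channels_6_clusters_order_2_gives_216(self):
        models = _models(4, 6)
        assign = np.zeros((10, 4), dtype=np.int64)
        conj = enumerate_conjunctions(models, assign)
        assert len(conj) == 216  # C(4,2) × 6 × 6

    def test_2_channels_2_clusters_gives_4(self):
        models = _models(2, 2)
        conj = enumerate_conjunctions(models, np.zeros((5, 2), dtype=np.int64))
        assert len(conj) == 4

    def test_toy_membership_brute_force(self):
        models = _models(2, 2)
        assign = np.array([[0, 1], [0, 0], [1, 1], [0, 1], [1, 0]])
        conj = dict((sc.parts, mask) for sc, mask in enumerate_conjunctions(models, assign))
        mask = conj[((0, 0), (1, 1))]
        brute = (assign[:, 0] == 0) & (assign[:, 1] == 1)
        np.testing.assert_array_equal(mask, brute)
        # conjunction membership ⊆ each parent single-channel membership
        assert np.all(mask <= (assign[:, 0] == 0))
        assert np.all(mask <= (assign[:, 1] == 1))

    def test_order_above_channel_count_errors(self):
        models = _models(2, 2)
        with pytest.raises(ValueError):
            enumerate_conjunctions(models, np.zeros((5, 2), dtype=np.int64), order=3)

    def test_order_3_count(self):
        models = _models(3, 2)
        conj = enumerate_conjunctions(models, np.zeros((5, 3), dtype=np.int64), order=3)
        assert len(conj) == 8  # C(3,3) × 2³


class TestEnrichment:
    def test_full_population_cluster_is_one(self):
        labels = np.array(["a"] * 30 + ["b"] * 70)
        x, _, n_c = enrichment(labels, np.ones(100, dtype=bool))
        assert n_c == 100
        assert x["a"] == pytest.approx(1.0) and x["b"] == pytest.approx(1.0)

    def test_pure_cluster_reciprocal_prevalence(self):
        labels = np.array(["a"] * 25 + ["b"] * 75)
        member = np.zeros(100, dtype=bool)
        member[:10] = True  # pure "a"
        x, _, _ = enrichment(labels, member)
        assert x["a"] == pytest.approx(4.0)  # 1 / 0.25
        assert x["b"] == 0.0

    def test_direct_arithmetic(self):
        # N(P,c)=30, N(·,c)=40, N(P,·)=100, N(·,·)=1000 → x = 7.5
        labels = np.array(["p"] * 100 + ["q"] * 900)
        member = np.zeros(1000, dtype=bool)
        member[:30] = True          # 30 of population p
        member[100:110] = True      # 10 of population q
        x, counts, n_c = enrichment(labels, member)
        assert (counts["p"], n_c) == (30, 40)
        assert x["p"] == pytest.approx(7.5)

    def test_empty_membership_flagged_nan(self):
        labels = np.array(["a", "b"])
        x, _, n_c = enrichment(labels, np.zeros(2, dtype=bool))
        assert n_c == 0 and np.isnan(x["a"]) and np.isnan(x["b"])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weighted_mean_identity(self, seed):
        # Σ_P x(P,c) · N(P,·) = N(·,·) for every non-empty cluster
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.choice(["a", "b", "c"], size=n)
        member = rng.random(n) < 0.4
        if not member.any() or len(np.unique(labels)) < 3:
            member[:3] = True
            labels[:3] = ["a", "b", "c"]
        x, _, _ = enrichment(labels, member)
        total = sum(x[p] * (labels == p).sum() for p in x)
        assert total == pytest.approx(n)

    def test_random_membership_enrichment_near_one(self):
        rng = np.random.default_rng(7)
        labels = rng.choice(["a", "b"], size=20_000, p=[0.3, 0.7])
        member = rng.random(20_000) < 0.5
        x, _, n_c = enrichment(labels, member)
        for p in ("a", "b"):
            assert abs(x[p] - 1.0) < 5 / np.sqrt(n_c * 0.3)

    def test_bounds_zero_to_xmax(self):
        rng = np.random.default_rng(8)
        labels = rng.choice(["a", "b", "c"], size=500, p=[0.2, 0.3, 0.5])
        for _ in range(20):
            member = rng.random(500) < rng.random()
            if not member.any():
                continue
            x, _, _ = enrichment(labels, member)
            for p in x:
                assert 0.0 <= x[p] <= max_achievable_enrichment(labels, p) + 1e-12


class TestMaxAchievableEnrichment:
    def test_prevalence_10_percent(self):
        labels = np.array(["p"] * 10 + ["q"] * 90)
        assert max_achievable_enrichment(labels, "p") == pytest.approx(10.0)

    def test_prevalence_100_percent(self):
        assert max_achievable_enrichment(np.array(["p"] * 5), "p") == pytest.approx(1.0)

    def test_mixed_sample(self):
        labels = np.array(["a"] * 100 + ["b"] * 300 + ["c"] * 600)
        assert max_achievable_enrichment(labels, "a") == pytest.approx(10.0)

    def test_absent_population_errors(self):
        with pytest.raises(ValueError):
            max_achievable_enrichment(np.array(["a"]), "zzz")


class TestRankAndSelect:
    def _toy_table(self):
        """Hand-built scenario: prevalence of 'p' is 0.25 (x_max = 4)."""
        rng = np.random.default_rng(0)
        labels = np.array(["p"] * 250 + ["q"] * 750)
        models = _models(2, 3)
        # craft assignments so cluster conjunctions have known compositions
        assign = np.zeros((1000, 2), dtype=np.int64)
        assign[:, 0] = rng.integers(0, 3, 1000)
        assign[:, 1] = rng.integers(0, 3, 1000)
        # make (0:0 & 1:0) nearly pure "p" and large
        assign[:200] = [0, 0]
        assign[200:260] = [1, 1]  # mixed
        conj = enumerate_conjunctions(models, assign)
        return labels, build_enrichment_table(conj, labels)

    def test_three_populations_defaults_give_nine(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(["a", "b", "c"], [500, 300, 200])
        models = _models(3, 4)
        # assignments correlated with labels so enrichment structure exists
        assign = rng.integers(0, 4, size=(1000, 3))
        assign[labels == "a", 0] = 0
        assign[labels == "b", 1] = 1
        assign[labels == "c", 2] = 2
        conj = enumerate_conjunctions(models, assign)
        table = build_enrichment_table(conj, labels)
        sel = rank_and_select(table)
        assert sum(len(r.selected) for r in sel.values()) == 9

    def test_threshold_ranking_members_and_order(self):
        labels, table = self._toy_table()
        sel = rank_and_select(table, threshold_frac=0.75)
        res = sel["p"]
        assert res.x_max == pytest.approx(4.0)
        # ranking B: only above-threshold clusters, ordered by size descending
        assert (res.ranking_size["x"] >= 0.75 * res.x_max - 1e-12).all()
        sizes = res.ranking_size["size_frac"].to_numpy()
        assert np.all(np.diff(sizes) <= 1e-12)

    def test_enrichment_ties_broken_by_size(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "cluster": ["c1", "c2", "c3"],
                "parts": [((0, 0),), ((0, 1),), ((0, 2),)],
                "population": ["p"] * 3,
                "n_pc": [10, 20, 2],
                "n_c": [10, 20, 4],
                "n_p_total": [250] * 3,
                "n_total": [1000] * 3,
                "x": [4.0, 4.0, 2.0],
                "size_frac": [0.01, 0.02, 0.004],
                "size_frac_singlet": [0.01, 0.02, 0.004],
            }
        )
        sel = rank_and_select(table, top_n=2)
        assert sel["p"].ranking_top.iloc[0]["cluster"] == "c2"  # larger wins the tie

    def test_underfilled_flagged(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "cluster": ["c1"],
                "parts": [((0, 0),)],
                "population": ["p"],
                "n_pc": [10],
                "n_c": [10],
                "n_p_total": [50],
                "n_total": [100],
                "x": [2.0],
                "size_frac": [0.1],
                "size_frac_singlet": [0.1],
            }
        )
        res = rank_and_select(table, top_n=3)["p"]
        assert res.underfilled and len(res.selected) == 1

    def test_empty_table_errors(self):
        import pandas as pd

        with pytest.raises(ValueError):
            rank_and_select(pd.DataFrame())
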