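import numpy as np
import pytest

from mapsort.clustering import ChannelModel
from mapsort.sortdef import SortCluster
from mapsort.sorter import TimingConfig, decide, decide_batch, reanalyze, run_sort


def _models():
    rng = np.random.default_rng(0)
    return [ChannelModel(c, rng.normal(size=(4, 5))) for c in range(2)]


class TestDecide:
    def test_event_at_both_centroids_full(self):
        models = _models()
        sc = SortCluster(((0, 2), (1, 3)))
        vecs = np.stack([models[0].centroids[2], models[1].centroids[3]])
        assert decide(vecs, sc, models) == "full"

    def test_one_of_two_parts_partial(self):
        models = _models()
        sc = SortCluster(((0, 2), (1, 3)))
        vecs = np.stack([models[0].centroids[2], models[1].centroids[0]])
        assert decide(vecs, sc, models) == "partial"

    def test_no_match_none(self):
        models = _models()
        sc = SortCluster(((0, 2), (1, 3)))
        vecs = np.stack([models[0].centroids[0], models[1].centroids[0]])
        assert decide(vecs, sc, models) == "none"

    def test_missing_channel_errors(self):
        models = _models()
        sc = SortCluster(((0, 0), (1, 0)))
        with pytest.raises(ValueError):
            decide(np.zeros((1, 5)), sc, models)

    def test_batch_matches_brute_force_set_logic(self):
        rng = np.random.default_rng(1)
        sc = SortCluster(((0, 1), (1, 2)))
        assign = rng.integers(0, 4, size=(1000, 2))
        got = decide_batch(assign, sc)
        for i in range(1000):
            hits = int(assign[i, 0] == 1) + int(assign[i, 1] == 2)
            expected = "full" if hits == 2 else ("partial" if hits == 1 else "none")
            assert got[i] == expected

    def test_batch_consistent_with_per_event_decide(self):
        rng = np.random.default_rng(2)
        models = _models()
        sc = SortCluster(((0, 1), (1, 2)))
        vecs = rng.normal(size=(50, 2, 5))
        from mapsort.clustering import assign_nearest

        assign = np.stack(
            [assign_nearest(vecs[:, c, :], models[c]) for c in range(2)], axis=1
        )
        batch = decide_batch(assign, sc)
        for i in range(50):
            assert decide(vecs[i], sc, models) == batch[i]


SC = SortCluster(((0, 0),))


def _run(t, match, timing=None, labels=None, **kw):
    """Helper: events match (cluster 0) or not (cluster 1)."""
    assign = np.where(np.asarray(match)[:, None], 0, 1).astype(np.int64)
    return run_sort(np.asarray(t, dtype=float), assign, SC, timing or TimingConfig(),
                    labels=None if labels is None else np.asarray(labels), **kw)


class TestRunSort:
    def test_lone_target_sorted(self):
        out = _run([0.01], [True], labels=["t"])
        assert list(out.sorted_ids) == [0]
        assert out.purity == {"t": 1.0}
        assert out.yield_fraction == 1.0

    def test_coincident_contaminant_cosorted(self):
        # target at t=0, non-target 100 µs later: engagement [200, 600] µs,
        # arrivals at 300 and 400 µs both fall inside → both deflected
        out = _run([0.0, 100e-6], [True, False], labels=["t", "c"])
        assert list(out.sorted_ids) == [0]
        assert list(out.contaminant_ids) == [1]
        assert out.purity == {"t": 0.5, "c": 0.5}

    def test_late_neighbour_escapes(self):
        # non-target 500 µs later arrives at 800 µs, after disengagement
        out = _run([0.0, 500e-6], [True, False], labels=["t", "c"])
        assert list(out.contaminant_ids) == []
        assert out.purity == {"t": 1.0}

    def test_refractory_drops_second_trigger(self):
        out = _run([0.0, 1e-3], [True, True])
        assert list(out.dropped_ids) == [1]
        assert out.n_cycles == 1

    def test_saturation_cycle_rate_approaches_inverse_refractory(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(1 / 20_000, 20_000))  # ~1 s of saturated triggers
        out = _run(t, np.ones(t.size, dtype=bool))
        assert out.cycle_rate == pytest.approx(1 / 3.33e-3, rel=0.02)

    def test_sorted_and_dropped_disjoint_and_partition(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.exponential(1 / 2000, 3000))
        match = rng.random(3000) < 0.3
        out = _run(t, match)
        assert np.intersect1d(out.sorted_ids, out.dropped_ids).size == 0
        assert out.n_full + out.n_partial + out.n_none == 3000

    def test_low_rate_no_coincidence_exact_composition(self):
        # gaps far above the refractory window: every full match sorted alone
        rng = np.random.default_rng(2)
        t = np.arange(300) * 0.1
        match = rng.random(300) < 0.5
        out = _run(t, match)
        np.testing.assert_array_equal(out.sorted_ids, np.flatnonzero(match))
        assert out.contaminant_ids.size == 0
        assert out.yield_fraction == 1.0

    def test_unordered_stream_errors(self):
        with pytest.raises(ValueError):
            _run([1.0, 0.5], [True, True])

    def test_decision_rate_independent(self):
        rng = np.random.default_rng(3)
        match = rng.random(500) < 0.4
        t = np.cumsum(rng.exponential(1 / 100, 500))
        a = _run(t, match)
        b = _run(t * 10, match)  # 10× slower stream, same decisions
        assert a.n_full == b.n_full and a.n_partial == b.n_partial

    def test_purity_degrades_with_rate(self):
        rng = np.random.default_rng(4)
        n = 4000
        match = rng.random(n) < 0.2
        labels = np.where(match, "t", "c")
        gaps = rng.exponential(1.0, n)
        purities = []
        for rate in (50, 300, 1000, 3000):
            t = np.cumsum(gaps / rate)
            out = _run(t, match, labels=labels)
            purities.append(out.purity.get("t", 0.0))
        assert all(b <= a for a, b in zip(purities, purities[1:]))

    def test_timing_invariants_enforced(self):
        with pytest.raises(ValueError):
            TimingConfig(travel_time=100e-6)  # shorter than the actuation delay
        with pytest.raises(ValueError):
            TimingConfig(refractory=-1.0)


class TestReanalyze:
    def test_pure_sorted_sample(self):
        labels = np.array(["t"] * 25 + ["c"] * 75)
        out = _run([0.01], [True], labels=["t"])
        # put the single sorted event into the bigger labelled sample
        out.sorted_ids = np.array([0])
        rep = reanalyze(out, labels)
        assert rep["fractions"]["t"] == 1.0
        assert rep["enrichment"]["t"] == pytest.approx(4.0)  # prevalence 25%

    def test_representative_sample_enrichment_one(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["a", "b"], 1000, p=[0.3, 0.7])
        out = _run([0.01], [True])
        out.sorted_ids = np.arange(1000)  # deflected set = whole sample
        rep = reanalyze(out, labels)
        assert rep["enrichment"]["a"] == pytest.approx(1.0)
        assert rep["enrichment"]["b"] == pytest.approx(1.0)

    def test_toy_counts(self):
        labels = np.array(["a", "a", "b", "b", "b", "c", "c", "c", "c", "c"])
        out = _run([0.01], [True])
        out.sorted_ids = np.array([0, 2, 3, 5])
        rep = reanalyze(out, labels)
        assert rep["n_sorted"] == 4
        assert rep["fractions"] == {"a": 0.25, "b": 0.5, "c": 0.25}

    def test_empty_outcome_flagged(self):
        out = _run([0.01], [False])
        rep = reanalyze(out, np.array(["a"]))
        assert rep["empty"] is True
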