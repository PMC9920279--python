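import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odcss.clustering import (
    Cluster,
    ClusterMember,
    ODCState,
    cluster_center,
    distances_to_centers,
    euclidean_distance,
    odc_step,
    prune_pseudo_samples,
    spatio_temporal_weights,
)
from odcss.config import RunConfig
from odcss.stream import StreamSample

from conftest import make_samples
from oracles import reference_odc


def member(x, tick=0, provenance="unlabeled", y=None):
    return ClusterMember(
        sample=StreamSample(t=tick, x=np.atleast_1d(np.asarray(x, dtype=float))),
        insert_tick=tick,
        provenance=provenance,
        y=y,
    )


class TestDistanceAndCenter:
    def test_three_four_five_triangle(self):
        assert euclidean_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_identity_and_mismatch(self):
        x = np.array([1.0, 2.0])
        assert euclidean_distance(x, x) == 0.0
        with pytest.raises(ValueError):
            euclidean_distance(x, np.array([1.0]))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=10, max_size=10))
    def test_matches_loopwise_oracle(self, values):
        a, b = np.array(values[:5]), np.array(values[5:])
        loop = np.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
        assert abs(euclidean_distance(a, b) - loop) < 1e-9

    def test_center_examples(self):
        np.testing.assert_allclose(
            cluster_center([member([0.0, 0.0]), member([2.0, 2.0])]), [1.0, 1.0]
        )
        np.testing.assert_allclose(cluster_center([member([7.0])]), [7.0])
        with pytest.raises(ValueError, match="empty"):
            cluster_center([])

    def test_center_matches_accumulation_oracle(self):
        rng = np.random.default_rng(11)
        xs = rng.normal(size=(10, 4))
        members = [member(x, tick=i) for i, x in enumerate(xs)]
        acc = np.zeros(4)
        for x in xs:
            acc += x
        np.testing.assert_allclose(cluster_center(members), acc / 10, atol=1e-12)

    def test_distances_to_centers(self, state_1d):
        assert distances_to_centers(state_1d, np.array([1.0])).size == 0
        state_1d._new_cluster(np.array([0.0]), [member(0.0)])
        state_1d._new_cluster(np.array([10.0]), [member(10.0, tick=1)])
        np.testing.assert_allclose(
            distances_to_centers(state_1d, np.array([1.0])), [1.0, 9.0]
        )


class TestAssignment:
    def _seeded_state(self):
        cfg = RunConfig(R=1.0, M=2, seed=0)
        state = ODCState(config=cfg)
        odc_step(state, StreamSample(t=0, x=np.array([0.0])))
        return state

    def test_deep_insertion_updates_center_by_running_mean(self):
        state = self._seeded_state()
        event = odc_step(state, StreamSample(t=1, x=np.array([0.5])))
        assert event.kind == "joined_clusters"
        cl = state.clusters[0]
        assert cl.n == 2
        np.testing.assert_allclose(cl.c, [0.25])  # (0*1 + 0.5)/2

    def test_shallow_insertion_keeps_center(self):
        state = self._seeded_state()
        event = odc_step(state, StreamSample(t=1, x=np.array([0.9])))
        assert event.kind == "joined_clusters"
        np.testing.assert_allclose(state.clusters[0].c, [0.0])
        assert state.clusters[0].n == 2

    def test_beyond_radius_becomes_outlier(self):
        state = self._seeded_state()
        event = odc_step(state, StreamSample(t=1, x=np.array([1.5])))
        assert event.kind == "became_outlier"
        assert len(state.outliers) == 1

    def test_multi_membership_within_overlapping_clusters(self):
        cfg = RunConfig(R=1.0, M=2, seed=0)
        state = ODCState(config=cfg, seeded=True)
        state._new_cluster(np.array([0.0]), [member(0.0)])
        state._new_cluster(np.array([1.4]), [member(1.4, tick=1)])
        event = odc_step(state, StreamSample(t=2, x=np.array([0.7])))
        assert sorted(event.cluster_ids) == [0, 1]
        assert all(any(m.tick == 2 for m in cl.members) for cl in state.clusters)


class TestClusterBirth:
    def _state(self, M):
        cfg = RunConfig(R=1.0, M=M, seed=0)
        return ODCState(config=cfg, seeded=True)

    def test_birth_at_threshold(self):
        state = self._state(M=2)
        odc_step(state, StreamSample(t=0, x=np.array([5.0])))
        event = odc_step(state, StreamSample(t=1, x=np.array([5.4])))
        assert event.kind == "new_cluster_formed"
        assert len(state.clusters) == 1
        np.testing.assert_allclose(state.clusters[0].c, [5.2])
        assert state.outliers == []

    def test_below_threshold_keeps_buffer(self):
        state = self._state(M=3)
        odc_step(state, StreamSample(t=0, x=np.array([5.0])))
        event = odc_step(state, StreamSample(t=1, x=np.array([5.4])))
        assert event.kind == "became_outlier"
        assert len(state.outliers) == 2

    def test_distant_outlier_left_behind(self):
        state = self._state(M=2)
        odc_step(state, StreamSample(t=0, x=np.array([5.0])))
        odc_step(state, StreamSample(t=1, x=np.array([20.0])))
        event = odc_step(state, StreamSample(t=2, x=np.array([5.4])))
        assert event.kind == "new_cluster_formed"
        assert sorted(m.tick for m in state.clusters[0].members) == [0, 2]
        assert [r.sample.t for r in state.outliers] == [1]


class TestSpatioTemporalWeights:
    def test_hand_evaluation(self):
        # distances (1, 3) from center 0; ages (2, 2) at query tick 2
        cl = Cluster(id=0, c=np.array([0.0]),
                     members=[member(1.0, tick=0), member(-3.0, tick=0)])
        w = spatio_temporal_weights(cl, query_tick=2, alpha=0.5)
        np.testing.assert_allclose(w, [1.125, 1.375])

    def test_alpha_limits(self):
        cl = Cluster(id=0, c=np.array([0.0]),
                     members=[member(1.0, tick=4), member(-3.0, tick=0)])
        spatial = spatio_temporal_weights(cl, query_tick=6, alpha=1.0)
        np.testing.assert_allclose(spatial, [0.25, 0.75])  # d/sum(d) only
        temporal = spatio_temporal_weights(cl, query_tick=6, alpha=0.0)
        # ages (2, 6): sum 8 -> factors (4, 4/3); newer sample more protected
        np.testing.assert_allclose(temporal, [4.0, 4.0 / 3.0])
        assert temporal[0] > temporal[1]

    def test_degenerate_cases_never_nan(self):
        single = Cluster(id=0, c=np.array([1.0]), members=[member(1.0)])
        np.testing.assert_allclose(spatio_temporal_weights(single, 5, 0.5), [1.0])
        # all members at the center, all inserted at the query tick
        degen = Cluster(id=1, c=np.array([2.0]),
                        members=[member(2.0, tick=3), member(2.0, tick=3)])
        w = spatio_temporal_weights(degen, query_tick=3, alpha=0.7)
        assert np.isfinite(w).all()
        # zero-age member takes the max temporal factor of the aged ones
        mix = Cluster(id=2, c=np.array([0.0]),
                      members=[member(1.0, tick=0), member(2.0, tick=4)])
        w = spatio_temporal_weights(mix, query_tick=4, alpha=0.0)
        assert w[1] == pytest.approx(w[0])


class TestPruning:
    def _state_with_cluster(self, members, P=0.5, alpha=0.5):
        cfg = RunConfig(R=1.0, M=2, P=P, alpha=alpha, seed=0)
        state = ODCState(config=cfg, seeded=True)
        state._new_cluster(cluster_center(members), list(members))
        return state

    def test_removes_smallest_weight_pseudo_members(self):
        members = [member(x, tick=t, provenance="pseudo", y=0.0)
                   for t, x in enumerate([0.1, 0.2, 3.0, 4.0])]
        state = self._state_with_cluster(members, P=0.5)
        cl = state.clusters[0]
        weights = spatio_temporal_weights(cl, 10, 0.5)
        expected_removed = {cl.members[i].tick
                            for i in np.argsort(weights, kind="stable")[:2]}
        event = prune_pseudo_samples(state, [0], query_tick=10)
        assert set(event.details["removed_ticks"][0]) == expected_removed
        assert state.clusters[0].n == 2

    def test_labeled_members_never_pruned(self):
        members = [member(x, tick=t, provenance="labeled", y=1.0)
                   for t, x in enumerate([0.0, 0.5, 1.0])]
        state = self._state_with_cluster(members, P=1.0)
        event = prune_pseudo_samples(state, [0], query_tick=5)
        assert state.clusters[0].n == 3
        assert event.details["removed_provenances"] == []

    def test_zero_proportion_is_noop(self):
        members = [member(x, tick=t, provenance="pseudo", y=0.0)
                   for t, x in enumerate([0.0, 1.0])]
        state = self._state_with_cluster(members, P=0.0)
        prune_pseudo_samples(state, [0], query_tick=5)
        assert state.clusters[0].n == 2

    def test_post_pruning_eligible_count(self):
        for n_eligible, P in [(5, 0.5), (7, 0.3), (4, 0.9)]:
            members = [member(float(i), tick=i, provenance="pseudo", y=0.0)
                       for i in range(n_eligible)]
            members.append(member(0.5, tick=99, provenance="labeled", y=1.0))
            state = self._state_with_cluster(members, P=P)
            prune_pseudo_samples(state, [0], query_tick=100)
            eligible_left = sum(
                1 for m in state.clusters[0].members if m.provenance != "labeled"
            )
            assert eligible_left == int(np.ceil((1 - P) * n_eligible))


class TestODCStep:
    def test_first_sample_seeds_initial_cluster(self, state_1d):
        event = odc_step(state_1d, StreamSample(t=0, x=np.array([3.0])))
        assert event.kind == "new_cluster_formed"
        assert event.details.get("initial") is True
        assert len(state_1d.clusters) == 1
        np.testing.assert_allclose(state_1d.clusters[0].c, [3.0])

    def test_six_sample_hand_trace(self, state_1d):
        xs = [0.0, 0.5, 0.9, 5.0, 5.4, 5.2]
        kinds = []
        for i, x in enumerate(xs):
            kinds.append(odc_step(state_1d, StreamSample(t=i, x=np.array([x]))).kind)
        assert kinds == [
            "new_cluster_formed", "joined_clusters", "joined_clusters",
            "became_outlier", "new_cluster_formed", "joined_clusters",
        ]
        assert len(state_1d.clusters) == 2
        assert state_1d.outliers == []
        np.testing.assert_allclose(state_1d.clusters[0].c, [1.4 / 3])
        np.testing.assert_allclose(state_1d.clusters[1].c, [5.2])

    def test_replay_determinism(self):
        rng = np.random.default_rng(5)
        samples = make_samples(list(rng.normal(size=(40, 2))))
        finals = []
        for _ in range(2):
            state = ODCState(config=RunConfig(R=1.5, M=3, seed=0))
            for s in samples:
                odc_step(state, s)
            finals.append(state)
        a, b = finals
        assert len(a.clusters) == len(b.clusters)
        for ca, cb in zip(a.clusters, b.clusters):
            np.testing.assert_array_equal(ca.c, cb.c)
            assert [m.tick for m in ca.members] == [m.tick for m in cb.members]
        assert [r.sample.t for r in a.outliers] == [r.sample.t for r in b.outliers]


class TestAgainstReferenceTranscription:
    @pytest.mark.parametrize("seed", range(5))
    def test_final_states_match(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of three blobs plus sprinkled noise, 2-D
        xs = np.vstack([
            rng.normal([0, 0], 0.8, size=(70, 2)),
            rng.normal([6, 6], 0.8, size=(70, 2)),
            rng.uniform(-4, 10, size=(60, 2)),
        ])
        rng.shuffle(xs)
        samples = make_samples(list(xs))
        R, M = 1.5, 4
        state = ODCState(config=RunConfig(R=R, M=M, seed=0))
        for s in samples:
            odc_step(state, s)
        ref_clusters, ref_outliers = reference_odc(samples, R, M)
        assert len(state.clusters) == len(ref_clusters)
        for cl, ref in zip(state.clusters, ref_clusters):
            np.testing.assert_allclose(cl.c, ref["c"], atol=1e-9)
            assert [m.tick for m in cl.members] == ref["ticks"]
        assert [r.sample.t for r in state.outliers] == ref_outliers


class TestSnapshot:
    def test_snapshot_counts_by_provenance(self, state_1d):
        from odcss.clustering import cluster_snapshot

        state_1d._new_cluster(np.array([0.0]), [
            member(0.0, tick=0, provenance="labeled", y=1.0),
            member(0.1, tick=1, provenance="pseudo", y=0.9),
            member(0.2, tick=2),
        ])
        df = cluster_snapshot(state_1d)
        assert list(df["id"]) == [0]
        assert df.loc[0, "n"] == 3
        assert df.loc[0, "n_labeled"] == 1
        assert df.loc[0, "n_pseudo"] == 1
        assert df.loc[0, "n_unlabeled"] == 1
        assert df.loc[0, "c0"] == 0.0


class TestEventContracts:
    def test_insertion_distances_and_birth_sizes(self):
        rng = np.random.default_rng(2)
        xs = np.vstack([rng.normal([0, 0], 1.0, size=(60, 2)),
                        rng.normal([5, 5], 1.0, size=(60, 2))])
        rng.shuffle(xs)
        cfg = RunConfig(R=1.5, M=4, seed=0)
        state = ODCState(config=cfg)
        for s in make_samples(list(xs)):
            odc_step(state, s)
        joined = [e for e in state.events if e.kind == "joined_clusters"]
        assert joined, "expected at least one in-cluster insertion"
        for e in joined:
            assert all(d <= cfg.R + 1e-12 for d in e.details["insert_distances"])
        births = [e for e in state.events if e.kind == "new_cluster_formed"]
        for e in births:
            if e.details.get("initial"):
                assert e.details["birth_size"] == 1
            else:
                assert e.details["birth_size"] >= cfg.M
        outlier_events = [e for e in state.events if e.kind == "became_outlier"]
        for e in outlier_events:
            assert all(d > cfg.R for d in e.details["outlier_distances"])
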