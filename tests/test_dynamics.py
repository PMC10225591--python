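import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnda.dynamics import (
    build_feature_matrix,
    cluster_transitions,
    consensus_cluster,
    cosine_distance,
    embedding_distance,
    ensemble_dynamics,
    extreme_dynamics,
    node_dynamics,
    run_mnda,
)
from mnda.ednn import EDNNConfig
from mnda.isn import ISNSet
from mnda.multiplex import MultiplexNetwork

from conftest import random_weighted_graph

FAST = EDNNConfig(epochs=60, learning_rate=3e-3)


class TestCosineDistance:
    def test_identical_vectors_zero(self):
        assert cosine_distance([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)

    def test_opposite_vectors_two(self):
        assert cosine_distance([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(2.0)

    def test_orthogonal_vectors_one(self):
        assert cosine_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])

    def test_embedding_convention_for_zero_vectors(self):
        assert embedding_distance([0.0, 0.0], [0.0, 0.0]) == 0.0
        with pytest.warns(UserWarning):
            assert embedding_distance([0.0, 0.0], [1.0, 0.0]) == 2.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    def test_range_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            return
        d = cosine_distance(a, b)
        assert 0.0 <= d <= 2.0


class TestNodeDynamics:
    def test_identical_layers_give_zero_distances(self, rng):
        w = random_weighted_graph(rng, k=8)
        mpx = MultiplexNetwork([f"n{i}" for i in range(8)], [w, w.copy()], ["t1", "t2"])
        result = run_mnda([mpx], config=FAST, seed=0)
        assert np.allclose(result.dynamics["distance"].to_numpy(), 0.0, atol=1e-12)

    def test_one_value_per_owner_node(self, rng):
        w1, w2 = random_weighted_graph(rng, 6), random_weighted_graph(rng, 6)
        mpx = MultiplexNetwork([f"n{i}" for i in range(6)], [w1, w2], ["t1", "t2"], owner="x")
        result = run_mnda([mpx], config=FAST, seed=0)
        assert len(result.dynamics) == 6
        assert result.dynamics.index.get_level_values("owner").unique().tolist() == ["x"]

    def test_missing_layer_entries_rejected(self, rng):
        from mnda.ednn import EmbeddingSet

        idx = pd.MultiIndex.from_tuples(
            [("o", "t1", "a"), ("o", "t1", "b"), ("o", "t2", "a")],
            names=["owner", "layer", "node"],
        )
        emb = EmbeddingSet(pd.DataFrame(np.ones((3, 2)), index=idx), FAST, 0.0)
        with pytest.raises(ValueError, match="missing"):
            node_dynamics(emb, ("t1", "t2"))


class TestEnsembleDynamics:
    def test_identical_seeds_give_identical_columns(self, rng):
        w1, w2 = random_weighted_graph(rng, 6), random_weighted_graph(rng, 6)
        mpx = MultiplexNetwork([f"n{i}" for i in range(6)], [w1, w2], ["t1", "t2"])
        df, _ = ensemble_dynamics([mpx], config=FAST, seeds=[5, 5], layer_pair=("t1", "t2"))
        assert np.array_equal(df["rep_0"].to_numpy(), df["rep_1"].to_numpy())

    def test_mean_column_is_arithmetic_mean(self, rng):
        w1, w2 = random_weighted_graph(rng, 6), random_weighted_graph(rng, 6)
        mpx = MultiplexNetwork([f"n{i}" for i in range(6)], [w1, w2], ["t1", "t2"])
        df, embs = ensemble_dynamics([mpx], config=FAST, seeds=[1, 2, 3], layer_pair=("t1", "t2"))
        reps = df[[c for c in df.columns if c.startswith("rep_")]]
        assert np.allclose(df["mean"], reps.mean(axis=1))
        assert len(embs) == 3

    def test_single_repeat_rejected(self, rng):
        w = random_weighted_graph(rng, 5)
        mpx = MultiplexNetwork([f"n{i}" for i in range(5)], [w, w], ["t1", "t2"])
        with pytest.raises(ValueError, match="n_repeats >= 2"):
            ensemble_dynamics([mpx], config=FAST, n_repeats=1)


class TestConsensusCluster:
    def blobs(self, rng, n_per=12, d=4, sep=8.0):
        a = rng.normal(0, 1, (n_per, d))
        b = rng.normal(sep, 1, (n_per, d))
        items = [f"p{i}" for i in range(2 * n_per)]
        return pd.DataFrame(np.vstack([a, b]), index=items)

    def test_two_blobs_recovered_from_repeat_list(self, rng):
        frames = [self.blobs(rng) + rng.normal(0, 0.05, (24, 4)) for _ in range(6)]
        frames = [pd.DataFrame(f.to_numpy(), index=frames[0].index) for f in frames]
        result = consensus_cluster(frames, k_range=(2, 3, 4))
        assert result.k == 2
        labels = result.labels.to_numpy()
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
        m = result.matrix.to_numpy()
        assert m[:12, :12].mean() > 0.95 and m[12:, 12:].mean() > 0.95
        assert m[:12, 12:].mean() < 0.05

    def test_identical_repeats_give_binary_consensus(self, rng):
        frame = self.blobs(rng)
        result = consensus_cluster([frame, frame.copy(), frame.copy()], k_range=(2, 3))
        vals = result.matrix.to_numpy()
        assert np.all(np.isin(vals, [0.0, 1.0]))

    def test_matrix_symmetric_unit_diagonal_in_unit_interval(self, rng):
        frames = [self.blobs(rng, sep=3.0) for _ in range(4)]
        frames = [pd.DataFrame(f.to_numpy(), index=frames[0].index) for f in frames]
        result = consensus_cluster(frames, k_range=(2, 3, 4))
        m = result.matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert ((m >= 0) & (m <= 1)).all()

    def test_single_repeat_rejected(self, rng):
        with pytest.raises(ValueError, match="at least two"):
            consensus_cluster([self.blobs(rng)])

    def test_resampling_mode_recovers_blobs(self, rng):
        frame = self.blobs(rng)
        result = consensus_cluster(frame, k_range=(2, 3, 4), n_repeats=30, seed=0)
        labels = result.labels.to_numpy()
        assert result.k == 2
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1


class TestTransitions:
    def labels(self, pairs):
        idx = pd.MultiIndex.from_tuples(
            [(n, l) for n, l, _ in pairs], names=["node", "layer"]
        )
        return pd.Series([c for _, _, c in pairs], index=idx)

    def test_stable_nodes_identity_matrix(self):
        pairs = [(f"n{i}", l, i % 2) for i in range(6) for l in ("t1", "t2")]
        tt = cluster_transitions(self.labels(pairs), ("t1", "t2"))
        assert np.allclose(tt.probabilities.to_numpy(), np.eye(2))

    def test_hand_computed_transition_probability(self):
        pairs = []
        for i in range(70):
            dest = 0 if i < 60 else 1  # 60 stay in cluster 0, 10 move
            pairs.append((f"n{i}", "t1", 0))
            pairs.append((f"n{i}", "t2", dest))
        tt = cluster_transitions(self.labels(pairs), ("t1", "t2"))
        assert tt.probabilities.loc[0, 0] == pytest.approx(6 / 7)
        assert tt.counts.loc[0, 1] == 10

    def test_rows_sum_to_one(self, rng):
        pairs = []
        for i in range(30):
            pairs.append((f"n{i}", "t1", int(rng.integers(3))))
            pairs.append((f"n{i}", "t2", int(rng.integers(3))))
        tt = cluster_transitions(self.labels(pairs), ("t1", "t2"))
        assert np.allclose(tt.probabilities.sum(axis=1).to_numpy(), 1.0)

    def test_missing_layer_label_rejected(self):
        pairs = [("a", "t1", 0), ("a", "t2", 0), ("b", "t1", 1)]
        with pytest.raises(ValueError, match="missing"):
            cluster_transitions(self.labels(pairs), ("t1", "t2"))


class TestExtremeDynamics:
    def test_single_obvious_jump(self):
        scores = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.9})
        res = extreme_dynamics(scores, q=0.5)
        assert res["high_ids"] == ["d"]

    def test_equally_spaced_scores_give_minimal_sets(self):
        scores = pd.Series(np.linspace(0, 1, 12), index=[f"n{i}" for i in range(12)])
        res = extreme_dynamics(scores, q=0.25)
        assert len(res["high_ids"]) <= 1 and len(res["low_ids"]) <= 1

    def test_constant_scores_give_empty_sets(self):
        scores = pd.Series(0.5, index=[f"n{i}" for i in range(8)])
        res = extreme_dynamics(scores, q=0.25)
        assert res["high_ids"] == [] and res["low_ids"] == []

    def test_high_low_disjoint(self, rng):
        scores = pd.Series(rng.random(40), index=[f"n{i}" for i in range(40)])
        res = extreme_dynamics(scores, q=0.5)
        assert not set(res["high_ids"]) & set(res["low_ids"])

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="4 nodes"):
            extreme_dynamics(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}), q=0.5)


class TestFeatureMatrix:
    def test_node_mode_has_2k_columns(self, toy_table):
        from mnda.io import clr_transform

        feats = build_feature_matrix("node", abundance=clr_transform(toy_table))
        assert feats.shape == (4, 6)  # 4 individuals x (3 taxa x 2 layers)
        assert "taxA@t1" in feats.columns and "taxC@t2" in feats.columns

    def test_dynamic_mode_has_k_columns(self):
        dyn = pd.DataFrame(
            np.random.default_rng(0).random((5, 3)),
            index=[f"i{k}" for k in range(5)],
            columns=["taxA", "taxB", "taxC"],
        )
        feats = build_feature_matrix("dynamic", dynamics=dyn)
        assert feats.shape == (5, 3)
        assert list(feats.columns) == ["taxA.dyn", "taxB.dyn", "taxC.dyn"]

    def test_edge_mode_column_count_and_order(self):
        nets = np.zeros((2, 3, 3))
        nets[:, 0, 1] = nets[:, 1, 0] = 0.5
        nets[:, 1, 2] = nets[:, 2, 1] = 0.3
        nets[:, 0, 2] = nets[:, 2, 0] = 0.1
        isnset = ISNSet(["b", "a", "c"], ["i0", "i1"], nets, n_reference=5, abs_applied=True)
        feats = build_feature_matrix("edge", isns={"t1": isnset, "t2": isnset})
        assert feats.shape == (2, 6)  # 3 edges x 2 layers
        assert list(feats.columns)[:3] == ["a--b@t1", "a--c@t1", "b--c@t1"]

    def test_missing_individual_rejected(self):
        dyn = pd.DataFrame(np.ones((2, 2)), index=["i0", "i1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            build_feature_matrix("dynamic", dynamics=dyn, individuals=["i0", "i9"])
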