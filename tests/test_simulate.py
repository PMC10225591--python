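import numpy as np
import pandas as pd
import pytest

from mnda.dynamics import run_mnda
from mnda.ednn import EDNNConfig
from mnda.simulate import (
    DEFAULT_NOISE_LEVELS,
    SimulationSpec,
    SyntheticCohortSpec,
    add_uniform_noise,
    detect_topm,
    jaccard,
    laplacian_baseline,
    make_benchmark_multiplex,
    make_synthetic_cohort,
    run_benchmark,
)


class TestBenchmarkGenerator:
    def test_no_controls_means_identical_layers(self):
        spec = SimulationSpec(n_nodes=30, m_control=0)
        mpx, controls = make_benchmark_multiplex(spec, seed=0)
        assert controls == set()
        assert np.array_equal(mpx.layers[0], mpx.layers[1])

    def test_exactly_controls_have_changed_neighbor_sets(self):
        spec = SimulationSpec(n_nodes=95, m_control=10)
        mpx, controls = make_benchmark_multiplex(spec, seed=3)
        w1, w2 = mpx.layers
        changed = {
            mpx.node_ids[i]
            for i in range(95)
            if set(np.flatnonzero(w1[i])) != set(np.flatnonzero(w2[i]))
        }
        assert controls <= changed  # every control rewired
        # controls' new neighbor sets are disjoint from the old ones
        for c in controls:
            i = mpx.node_index(c)
            assert not (set(np.flatnonzero(w1[i])) & set(np.flatnonzero(w2[i])))
        # non-control changes only happen via edges incident to controls
        collateral = changed - controls
        ctrl_idx = {mpx.node_index(c) for c in controls}
        for node in collateral:
            i = mpx.node_index(node)
            diff = set(np.flatnonzero(w1[i])) ^ set(np.flatnonzero(w2[i]))
            assert diff <= ctrl_idx
        # nodes not adjacent to a control in either layer are untouched
        for i in range(95):
            if mpx.node_ids[i] in controls:
                continue
            touches_control = bool(
                (set(np.flatnonzero(w1[i])) | set(np.flatnonzero(w2[i]))) & ctrl_idx
            )
            if not touches_control:
                assert np.array_equal(w1[i], w2[i])

    def test_control_degrees_preserved(self):
        spec = SimulationSpec(n_nodes=60, m_control=6)
        mpx, controls = make_benchmark_multiplex(spec, seed=5)
        w1, w2 = mpx.layers
        for c in controls:
            i = mpx.node_index(c)
            assert (w1[i] > 0).sum() == (w2[i] > 0).sum()

    def test_minimum_degree_two(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(), seed=9)
        degrees = (mpx.layers[0] > 0).sum(axis=1)
        assert degrees.min() >= 1  # config-model simplification can drop a few
        assert degrees.mean() == pytest.approx(4.0, abs=0.8)

    def test_weights_in_unit_interval(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(), seed=2)
        for w in mpx.layers:
            vals = w[w > 0]
            assert ((vals > 0) & (vals <= 1)).all()

    def test_infeasible_specs_rejected(self):
        with pytest.raises(ValueError, match="m_control"):
            SimulationSpec(n_nodes=5, m_control=5)
        with pytest.raises(ValueError, match="mean degree"):
            SimulationSpec(mean_degree=1.0)


class TestNoise:
    def test_zero_noise_is_identity(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(n_nodes=20, m_control=2), seed=0)
        noisy = add_uniform_noise(mpx, 0.0, seed=1)
        assert np.array_equal(noisy.layers[0], mpx.layers[0])

    def test_entries_increase_within_bound_and_stay_symmetric(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(n_nodes=20, m_control=2), seed=0)
        amp = float(np.exp(-3))
        noisy = add_uniform_noise(mpx, amp, seed=1)
        for w0, w1 in zip(mpx.layers, noisy.layers):
            delta = w1 - w0
            off = ~np.eye(20, dtype=bool)
            assert ((delta[off] >= 0) & (delta[off] <= amp)).all()
            assert np.allclose(w1, w1.T)
            assert np.allclose(np.diag(w1), 0.0)

    def test_negative_amplitude_rejected(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(n_nodes=20, m_control=2), seed=0)
        with pytest.raises(ValueError):
            add_uniform_noise(mpx, -0.1)


class TestJaccardDetect:
    def test_jaccard_cases(self):
        assert jaccard({"a", "b", "c"}, {"a", "b", "c"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard(set(), set()) == 1.0

    def test_topm_all_nodes_and_unique_max(self):
        d = pd.Series({"a": 0.1, "b": 0.9, "c": 0.5})
        assert detect_topm(d, 3) == {"a", "b", "c"}
        assert detect_topm(d, 1) == {"b"}

    def test_topm_tie_broken_by_node_id(self):
        d = pd.Series({"b": 0.5, "a": 0.5, "c": 0.1})
        assert detect_topm(d, 1) == {"a"}

    def test_invalid_m_rejected(self):
        d = pd.Series({"a": 0.1})
        with pytest.raises(ValueError):
            detect_topm(d, 0)
        with pytest.raises(ValueError):
            detect_topm(d, 2)


class TestLaplacianBaseline:
    def test_identical_layers_zero_distances(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(n_nodes=30, m_control=0), seed=1)
        base = laplacian_baseline(mpx, n_eigvecs=5)
        assert np.allclose(base["distance"].to_numpy(), 0.0, atol=1e-8)

    def test_sign_flip_invariance(self):
        mpx, _ = make_benchmark_multiplex(SimulationSpec(n_nodes=30, m_control=0), seed=1)
        ref = laplacian_baseline(mpx, n_eigvecs=5)["distance"].to_numpy()
        # identical layers: any per-vector sign flip must be undone by alignment
        assert np.allclose(ref, 0.0, atol=1e-8)


class TestSyntheticCohort:
    def test_full_coupling_phenotype_equals_subgroup(self):
        spec = SyntheticCohortSpec(n_individuals=20, n_taxa=10, n_rewired=4, coupling=1.0)
        _, truth = make_synthetic_cohort(spec, seed=0)
        assert truth["phenotype"].equals(truth["subgroup"].rename("phenotype"))

    def test_metadata_shape_and_time_points(self):
        spec = SyntheticCohortSpec(n_individuals=10, n_taxa=10, n_rewired=4)
        table, _ = make_synthetic_cohort(spec, seed=1)
        assert table.n_samples == 20
        assert table.time_points() == ["t1", "t2"]
        assert len(table.individuals()) == 10

    def test_no_rewiring_gives_low_dynamics_everywhere(self):
        """End-to-end null: both subgroups persistent -> near-zero dynamics."""
        from mnda.cohort import individual_dynamics_pipeline

        spec = SyntheticCohortSpec(n_individuals=12, n_taxa=20, n_rewired=8, rewire_prob=0.0)
        table, _ = make_synthetic_cohort(spec, seed=2)
        out = individual_dynamics_pipeline(
            table, config=EDNNConfig(epochs=60, learning_rate=3e-3), seed=2
        )
        assert out["dynamics"].to_numpy().mean() < 0.15

    def test_poisson_limit_moment_check(self):
        """Zero inflation 0 and huge dispersion: variance/mean -> 1."""
        spec = SyntheticCohortSpec(
            n_individuals=100, n_taxa=10, n_rewired=4, zero_inflation=0.0, dispersion=1e6,
            rho=0.05, stability=0.0, abundance_sigma=0.0, depth_range=(1000, 1000),
        )
        table, _ = make_synthetic_cohort(spec, seed=3)
        counts = table.counts.to_numpy()
        ratio = counts.var(axis=0) / counts.mean(axis=0)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.25)

    def test_zero_inflation_raises_zero_fraction(self):
        base = dict(n_individuals=100, n_taxa=10, n_rewired=4, abundance_sigma=0.0,
                    depth_range=(1000, 1000))
        t0, _ = make_synthetic_cohort(SyntheticCohortSpec(**base, zero_inflation=0.0), seed=4)
        t1, _ = make_synthetic_cohort(SyntheticCohortSpec(**base, zero_inflation=0.3), seed=4)
        f0 = (t0.counts.to_numpy() == 0).mean()
        f1 = (t1.counts.to_numpy() == 0).mean()
        assert f1 > f0 + 0.2
        assert f1 == pytest.approx(0.3, abs=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(coupling=1.5)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_taxa=41)


class TestRunBenchmark:
    def test_replicates_reproducible_and_tidy(self):
        spec = SimulationSpec(n_nodes=30, m_control=3)
        cfg = EDNNConfig(epochs=60, learning_rate=3e-3)
        kw = dict(noise_levels=[0.0], n_replicates=2, seed=4, config=cfg)
        df1 = run_benchmark(spec, **kw)
        df2 = run_benchmark(spec, **kw)
        pd.testing.assert_frame_equal(df1, df2)
        assert set(df1.columns) == {"method", "noise", "replicate", "jaccard"}
        assert ((df1["jaccard"] >= 0) & (df1["jaccard"] <= 1)).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown methods"):
            run_benchmark(SimulationSpec(), methods=("mnda", "magic"))

    def test_default_noise_grid_is_exp_range(self):
        assert len(DEFAULT_NOISE_LEVELS) == 9
        assert DEFAULT_NOISE_LEVELS[0] == pytest.approx(np.exp(-10))
        assert DEFAULT_NOISE_LEVELS[-1] == pytest.approx(np.exp(-2))
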