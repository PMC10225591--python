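import numpy as np
import pandas as pd
import pytest

from mnda.io import AbundanceTable, GlobalNetwork, clr_transform
from mnda.isn import (
    ISNSet,
    absolute_weights,
    directory_estimator,
    fallback_estimator,
    isn_average_check,
    lioness_isn,
    make_estimator,
    read_isns,
    write_isns,
)


def one_time_table(rng, n=6, k=4):
    counts = pd.DataFrame(
        rng.integers(1, 200, size=(n, k)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"t{j}" for j in range(k)],
    )
    meta = pd.DataFrame(
        {"individual_id": [f"i{i}" for i in range(n)], "time_point": "t1"},
        index=counts.index,
    )
    return AbundanceTable(counts, meta)


def constant_estimator(value=0.5):
    def est(table):
        k = table.n_taxa
        w = np.full((k, k), value)
        np.fill_diagonal(w, 0.0)
        return GlobalNetwork(table.taxon_ids, w, provenance="constant")

    return est


class TestLioness:
    def test_homogeneous_case_returns_global_weight(self, rng):
        """If every LOO network equals the global one, each ISN equals it too."""
        table = one_time_table(rng, n=10)
        isns = lioness_isn(table, constant_estimator(0.5))
        assert isns.n_reference == 10
        off = ~np.eye(table.n_taxa, dtype=bool)
        assert np.allclose(isns.networks[:, off], 0.5)

    def test_negativity_arithmetic(self):
        """N=5, w=0.4, w_loo=0.6 -> 5*0.4 - 4*0.6 = -0.4 (< 0 since w < (N-1)w_loo/N)."""
        n, w, w_loo = 5, 0.4, 0.6
        assert n * w - (n - 1) * w_loo == pytest.approx(-0.4)
        assert w < (n - 1) * w_loo / n  # the negativity condition

        class Flip:
            def __init__(self):
                self.calls = 0

            def __call__(self, table):
                value = 0.4 if table.n_samples == 5 else 0.6
                k = table.n_taxa
                m = np.full((k, k), value)
                np.fill_diagonal(m, 0.0)
                self.calls += 1
                return GlobalNetwork(table.taxon_ids, m)

        table = one_time_table(np.random.default_rng(0), n=5)
        isns = lioness_isn(table, Flip())
        assert isns.networks[0, 0, 1] == pytest.approx(-0.4)

    def test_matches_brute_force_recomputation(self, rng):
        """Edge weights equal an independently coded full/LOO correlation path."""
        table = one_time_table(rng, n=6, k=4)
        est = make_estimator("pearson_clr", sparsify_quantile=0.0)
        isns = lioness_isn(table, est)

        clr = clr_transform(table, 0.5).counts
        full = clr.corr(method="pearson").to_numpy()
        np.fill_diagonal(full, 0.0)
        n = table.n_samples
        for pos, ind in enumerate(isns.individual_ids):
            sample = table.metadata.index[table.metadata["individual_id"] == ind][0]
            loo = clr.drop(index=sample).corr(method="pearson").to_numpy()
            np.fill_diagonal(loo, 0.0)
            expected = n * full - (n - 1) * loo
            np.fill_diagonal(expected, 0.0)
            assert np.allclose(isns.networks[pos], expected, atol=1e-10)

    def test_estimator_called_n_plus_one_times(self, rng):
        table = one_time_table(rng, n=6)
        calls = {"n": 0}

        def counting(t):
            calls["n"] += 1
            return constant_estimator()(t)

        lioness_isn(table, counting)
        assert calls["n"] == 7

    def test_small_reference_rejected(self, rng):
        table = one_time_table(rng, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            lioness_isn(table, constant_estimator())

    def test_estimator_failure_names_individual(self, rng):
        table = one_time_table(rng, n=6)

        def flaky(t):
            if "s3" not in t.sample_ids:
                raise RuntimeError("boom")
            return constant_estimator()(t)

        with pytest.raises(RuntimeError, match="i3"):
            lioness_isn(table, flaky)

    def test_symmetry_and_zero_diagonal(self, rng):
        table = one_time_table(rng, n=8, k=5)
        isns = lioness_isn(table, make_estimator("pearson_clr"))
        for m in isns.networks:
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)


class TestAbsoluteWeights:
    def test_entrywise_absolute_and_idempotent(self, rng):
        table = one_time_table(rng, n=6)
        isns = lioness_isn(table, make_estimator("pearson_clr"))
        a1 = absolute_weights(isns)
        assert (a1.networks >= 0).all() and a1.abs_applied
        with pytest.warns(UserWarning, match="twice"):
            a2 = absolute_weights(a1)
        assert np.array_equal(a1.networks, a2.networks)

    def test_non_negative_input_unchanged(self):
        nets = np.array([[[0.0, 0.3], [0.3, 0.0]]])
        isns = ISNSet(["a", "b"], ["i0"], nets, n_reference=5)
        assert np.array_equal(absolute_weights(isns).networks, nets)


class TestAverageCheck:
    def test_linear_estimator_gives_exact_average(self, rng):
        """Mean-of-products estimators are linear in samples: deviation ~ 0."""
        table = one_time_table(rng, n=8, k=3)

        def product_mean(t):
            x = t.counts.to_numpy(dtype=float)
            w = x.T @ x / x.shape[0]
            np.fill_diagonal(w, 0.0)
            return GlobalNetwork(t.taxon_ids, w)

        isns = lioness_isn(table, product_mean)
        report = isn_average_check(isns, product_mean(table))
        assert report["max"] < 1e-9

    def test_pearson_estimator_small_but_nonzero(self, rng):
        table = one_time_table(rng, n=30, k=4)
        est = make_estimator("pearson_clr")
        isns = lioness_isn(table, est)
        report = isn_average_check(isns, est(table))
        assert 0 < report["max"] < 0.5

    def test_rejects_abs_transformed_input(self, rng):
        table = one_time_table(rng, n=6)
        est = make_estimator("pearson_clr")
        isns = absolute_weights(lioness_isn(table, est))
        with pytest.raises(ValueError, match="before absolute"):
            isn_average_check(isns, est(table))


class TestFallbackEstimator:
    def test_perfectly_correlated_pair(self):
        x = np.arange(1, 21, dtype=float)
        counts = pd.DataFrame({"a": x, "b": 2 * x})
        counts.index = [f"s{i}" for i in range(20)]
        net = fallback_estimator(AbundanceTable(counts), method="spearman")
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_sparsify_keeps_at_most_half(self, rng):
        table = one_time_table(rng, n=20, k=8)
        net = fallback_estimator(table, sparsify_quantile=0.5)
        total = 8 * 7 // 2
        nonzero = (net.weights[np.triu_indices(8, 1)] != 0).sum()
        assert nonzero <= total / 2

    def test_independent_noise_gives_small_weights(self, rng):
        # enough taxa that the compositional closure bias (~ -1/(K-1)) is small
        k = 20
        counts = pd.DataFrame(
            rng.poisson(100, size=(500, k)).astype(float),
            index=[f"s{i}" for i in range(500)],
            columns=[f"t{j}" for j in range(k)],
        )
        net = fallback_estimator(AbundanceTable(counts))
        off = np.abs(net.weights[np.triu_indices(k, 1)])
        assert off.mean() < 0.1
        assert np.median(off) < 0.1

    def test_constant_taxon_warns_and_zeroes(self, rng):
        counts = pd.DataFrame(
            {"a": rng.integers(1, 50, 10), "b": np.full(10, 7)},
            index=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="constant"):
            net = fallback_estimator(AbundanceTable(counts), method="spearman")
        assert net.weights[0, 1] == 0.0

    def test_provenance_flags_not_magma(self, rng):
        net = fallback_estimator(one_time_table(rng))
        assert "not MAGMA" in net.provenance


class TestPersistence:
    def test_isns_round_trip_via_directory(self, rng, tmp_path):
        table = one_time_table(rng, n=6)
        isns = absolute_weights(lioness_isn(table, make_estimator("pearson_clr")))
        write_isns(isns, tmp_path / "isns")
        back = read_isns(tmp_path / "isns")
        assert back.individual_ids == [str(i) for i in isns.individual_ids]
        assert np.allclose(back.networks, isns.networks, atol=1e-12)

    def test_directory_estimator_serves_global_and_loo(self, rng, tmp_path):
        from mnda.io import write_network
        import json

        table = one_time_table(rng, n=4, k=3)
        est = make_estimator("pearson_clr")
        d = tmp_path / "nets"
        d.mkdir()
        write_network(est(table), d / "global.tsv", fmt="edgelist")
        for ind in table.individuals():
            sample = table.metadata.index[table.metadata["individual_id"] == ind][0]
            write_network(est(table.drop_sample(sample)), d / f"loo_{ind}.tsv", fmt="edgelist")
        (d / "manifest.json").write_text(json.dumps({"individual_ids": table.individuals()}))
        from_dir = directory_estimator(d)
        direct = lioness_isn(table, est)
        served = lioness_isn(table, from_dir)
        assert np.allclose(direct.networks, served.networks, atol=1e-9)
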