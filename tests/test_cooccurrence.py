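import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncoocnet.cooccurrence import (
    NetworkConfig,
    bh_adjust,
    bootstrap_distribution,
    build_metadata_network,
    build_network,
    candidate_edges,
    is_stable,
    merge_pvalues,
    permutation_null,
    reboot_pvalue,
    spearman_score_matrix,
)
from ncoocnet.preprocess import to_relative_abundance
from ncoocnet.synthetic_community import SyntheticSpec, generate_dataset
from ncoocnet.tabular_io import AbundanceTable, SoilMetadata


def _frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T.astype(float)


class TestSpearmanMatrix:
    def test_monotone_pair(self):
        m = spearman_score_matrix(_frame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10]}))
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_antitone_pair(self):
        m = spearman_score_matrix(_frame({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]}))
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_rank_half(self):
        # ranks (1,2,3) vs (1,3,2): rho = 1 - 6*2/(3*8) = 0.5
        m = spearman_score_matrix(_frame({"a": [1, 2, 3], "b": [1, 3, 2]}))
        assert m.loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal(self, rng):
        x = pd.DataFrame(rng.random((6, 10)))
        m = spearman_score_matrix(x)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_matches_scipy(self, rng):
        x = pd.DataFrame(rng.random((5, 12)))
        m = spearman_score_matrix(x)
        ref = stats.spearmanr(x.to_numpy(), axis=1).statistic
        np.testing.assert_allclose(m.to_numpy(), ref, atol=1e-12)

    def test_constant_row_undefined(self):
        m = spearman_score_matrix(_frame({"a": [1, 1, 1], "b": [1, 2, 3]}))
        assert np.isnan(m.loc["a", "b"])
        assert m.loc["a", "a"] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            spearman_score_matrix(_frame({"a": [1, 2], "b": [2, 1]}))


class TestCandidateEdges:
    def _scores(self, r):
        return pd.DataFrame(
            [[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"]
        )

    def test_boundary_inclusive(self):
        assert candidate_edges(self._scores(0.70)) == [("a", "b")]

    def test_below_threshold_excluded(self):
        assert candidate_edges(self._scores(0.69)) == []

    def test_negative_included_two_sided(self):
        assert candidate_edges(self._scores(-0.85)) == [("a", "b")]

    def test_nan_excluded(self):
        assert candidate_edges(self._scores(np.nan)) == []

    def test_each_pair_once(self, rng):
        x = pd.DataFrame(rng.random((8, 5)))
        pairs = candidate_edges(spearman_score_matrix(x), threshold=0.01)
        assert len(pairs) == len({frozenset(p) for p in pairs})

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            candidate_edges(self._scores(0.9), threshold=0.0)


class TestPermutationNull:
    def test_independent_rows_null_centered(self, rng):
        x = pd.DataFrame(rng.random((30, 40)), index=[f"t{i}" for i in range(30)])
        x = x / x.sum(axis=0)
        null = permutation_null(
            x, ("t0", "t1"), n_iter=1000, renormalize=False, rng=rng
        )
        assert null.shape == (1000,)
        assert abs(np.nanmean(null)) < 0.05
        # the renormalized null keeps the (small, negative) compositional
        # bias by construction; it stays close to zero for 30 taxa
        null_rn = permutation_null(x, ("t0", "t1"), n_iter=1000, rng=rng)
        assert abs(np.nanmean(null_rn)) < 0.1

    def test_no_renormalize_matches_plain_shuffle(self, rng):
        # direct recomputation oracle: same seed stream, by-hand shuffles
        x = pd.DataFrame(rng.random((2, 10)), index=["a", "b"])
        seed = 99
        null = permutation_null(
            x, ("a", "b"), n_iter=500, renormalize=False,
            rng=np.random.default_rng(seed),
        )
        oracle_rng = np.random.default_rng(seed)
        xa, xb = x.loc["a"].to_numpy(), x.loc["b"].to_numpy()
        perms_a = np.argsort(oracle_rng.random((500, 10)), axis=1)
        perms_b = np.argsort(oracle_rng.random((500, 10)), axis=1)
        expected = np.array([
            stats.spearmanr(xa[pa], xb[pb]).statistic
            for pa, pb in zip(perms_a, perms_b)
        ])
        np.testing.assert_allclose(null, expected, atol=1e-12)

    def test_single_iteration_in_range(self, rng):
        x = pd.DataFrame(rng.random((3, 8)))
        x.index = ["a", "b", "c"]
        null = permutation_null(x, ("a", "b"), n_iter=1, rng=rng)
        assert null.shape == (1,)
        assert -1 <= null[0] <= 1

    def test_exact_enumeration_matches_sampled(self, rng):
        # oracle equivalence at n=4: 24^2 = 576 row-order pairs
        x = pd.DataFrame(rng.random((4, 4)), index=list("abcd"))
        x = x / x.sum(axis=0)
        exact = permutation_null(x, ("a", "b"), exact=True, renormalize=True)
        assert exact.shape == (576,)
        sampled = permutation_null(
            x, ("a", "b"), n_iter=4000, renormalize=True,
            rng=np.random.default_rng(5),
        )
        assert abs(np.nanmean(exact) - np.nanmean(sampled)) < 0.03

    def test_metadata_row_never_renormalized(self, rng):
        # direct recomputation oracle: the taxon row is re-closed against
        # the other taxa, the metadata row enters raw
        n = 10
        vals = rng.random((4, n))
        x = pd.DataFrame(vals, index=["t0", "t1", "t2", "m"])
        x.iloc[:3] = x.iloc[:3] / x.iloc[:3].sum(axis=0)
        seed = 123
        null = permutation_null(
            x, ("t0", "m"), n_iter=200, renormalize=True,
            metadata_rows={"m"}, rng=np.random.default_rng(seed),
        )
        oracle_rng = np.random.default_rng(seed)
        xt = x.loc["t0"].to_numpy()
        xm = x.loc["m"].to_numpy()
        rest = x.iloc[:3].sum(axis=0).to_numpy() - xt
        perms_t = np.argsort(oracle_rng.random((200, n)), axis=1)
        perms_m = np.argsort(oracle_rng.random((200, n)), axis=1)
        expected = np.array([
            stats.spearmanr(xt[pt] / (rest + xt[pt]), xm[pm]).statistic
            for pt, pm in zip(perms_t, perms_m)
        ])
        np.testing.assert_allclose(null, expected, atol=1e-12)

    def test_constant_row_rejected(self):
        x = _frame({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant"):
            permutation_null(x, ("a", "b"), n_iter=10)

    def test_renormalization_shifts_null_for_dominant_taxa(self, rng):
        # compositional effect: two dominant taxa shuffled and re-closed
        # acquire negative dependence, so the renormalized null mean
        # sits below the raw-shuffle null mean
        n = 30
        base = rng.random((2, n)) * 10 + 5
        minor = rng.random((3, n)) * 0.1
        x = pd.DataFrame(np.vstack([base, minor]), index=list("abcde"))
        x = x / x.sum(axis=0)
        renorm = permutation_null(
            x, ("a", "b"), n_iter=2000, renormalize=True,
            rng=np.random.default_rng(1),
        )
        raw = permutation_null(
            x, ("a", "b"), n_iter=2000, renormalize=False,
            rng=np.random.default_rng(1),
        )
        assert np.nanmean(renorm) < np.nanmean(raw) - 0.05


class TestBootstrap:
    def test_perfect_pair_invariant(self, rng):
        x = _frame({"a": [1, 2, 3, 4, 5, 6], "b": [2, 4, 6, 8, 10, 12]})
        boot = bootstrap_distribution(x, ("a", "b"), n_iter=200, rng=rng)
        ok = boot[np.isfinite(boot)]
        assert len(ok) > 0
        np.testing.assert_allclose(ok, 1.0)

    def test_boot_mean_tracks_observed(self):
        rng = np.random.default_rng(42)
        z = rng.standard_normal((2, 40))
        rho = 0.92
        y = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
        x = pd.DataFrame({"a": z[0], "b": y}).T
        obs = stats.spearmanr(z[0], y).statistic
        boot = bootstrap_distribution(x, ("a", "b"), n_iter=1000, rng=rng)
        assert abs(np.nanmean(boot) - obs) < 0.05

    def test_zero_iterations_rejected(self, rng):
        x = _frame({"a": [1, 2, 3], "b": [3, 2, 1]})
        with pytest.raises(ValueError, match="n_iter"):
            bootstrap_distribution(x, ("a", "b"), n_iter=0, rng=rng)

    def test_too_few_samples_rejected(self, rng):
        x = _frame({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError, match="3 samples"):
            bootstrap_distribution(x, ("a", "b"), rng=rng)


class TestRebootPvalue:
    def test_z_of_eight(self):
        null = np.array([-0.1, 0.1])  # mean 0
        boot = 0.8 + 0.1 * np.array([-1.0, 1.0]) / np.sqrt(2)  # mean .8, sd .1
        p = reboot_pvalue(null, boot)
        assert p == pytest.approx(2 * stats.norm.sf(8.0), rel=1e-9)
        assert p < 1e-10

    def test_identical_distributions(self, rng):
        v = rng.random(100)
        assert reboot_pvalue(v, v) == pytest.approx(1.0)

    def test_equal_means_nonzero_sd(self):
        null = np.array([0.4, 0.6])
        boot = np.array([0.3, 0.7])
        assert reboot_pvalue(null, boot) == pytest.approx(1.0)

    def test_degenerate_bootstrap_indicator(self):
        boot = np.array([0.5, 0.5, 0.5])
        assert reboot_pvalue(np.array([0.5, 0.5]), boot) == 1.0
        assert reboot_pvalue(np.array([0.1, 0.1]), boot) == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            reboot_pvalue(np.array([np.nan, np.nan]), np.array([0.1, 0.2]))

    def test_empirical_method_in_unit_interval(self, rng):
        null = rng.normal(0, 0.2, 500)
        boot = rng.normal(0.8, 0.1, 500)
        p = reboot_pvalue(null, boot, method="empirical")
        assert 0 < p <= 1
        assert p < 0.01


class TestStability:
    def test_null_mean_outside_interval_stable(self):
        boot = np.linspace(0.6, 0.9, 100)
        assert is_stable(boot, 0.0)

    def test_symmetric_bootstrap_unstable(self, rng):
        boot = rng.normal(0.0, 0.1, 1000)
        assert not is_stable(boot, 0.0)

    def test_ci_zero_degenerates_to_median(self):
        boot = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert not is_stable(boot, 3.0, ci=0.0)  # equals median -> unstable
        assert is_stable(boot, 2.9, ci=0.0)


class TestMergePvalues:
    def test_single_measure_identity(self):
        assert merge_pvalues([0.03]) == 0.03

    def test_perfectly_dependent_collapses(self):
        # cov(-2 ln p) = var = 4 for identical measures
        cov = np.array([[4.0, 4.0], [4.0, 4.0]])
        for p in (0.01, 0.2, 0.5, 0.9):
            assert merge_pvalues([p, p], cov=cov) == pytest.approx(p, rel=1e-6)

    def test_independent_is_fisher(self):
        # chi2_4 tail of -2(ln .5 + ln .5); oracle computed independently
        expected = stats.chi2.sf(-2 * (np.log(0.5) + np.log(0.5)), 4)
        assert merge_pvalues([0.5, 0.5]) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.5965735903, rel=1e-6)

    def test_empirical_cov_from_shared_null(self, rng):
        # identical score vectors -> fully dependent -> collapse toward p
        v = rng.normal(size=2000)
        merged = merge_pvalues([0.2, 0.2], null_scores=[v, v])
        assert merged == pytest.approx(0.2, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_pvalues([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            merge_pvalues([1.2])


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_one(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_monotone_in_p_order(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_capped_at_one(self):
        assert (bh_adjust([0.9, 0.95, 1.0]) <= 1.0).all()


def _synthetic_table(seed, n_taxa=30, n_samples=40, planted=(), depth=100_000):
    spec = SyntheticSpec(
        n_taxa=n_taxa, n_groups=1, n_replicates=n_samples, depth=depth,
        planted_edges=list(planted), seed=seed,
    )
    table, metadata, truth = generate_dataset(spec)
    return table, metadata, truth


class TestBuildNetwork:
    def test_planted_pair_recovered(self):
        table, _, _ = _synthetic_table(7, planted=[(0, 1, 0.95)])
        net = build_network(table, "G1", NetworkConfig(seed=7))
        assert set(net.graph.edges) == {("OTU_1", "OTU_2")}
        assert net.graph.edges["OTU_1", "OTU_2"]["sign"] == "positive"
        assert net.graph.edges["OTU_1", "OTU_2"]["q"] <= 0.05

    def test_negative_planted_pair_negative_sign(self):
        table, _, _ = _synthetic_table(13, planted=[(2, 5, -0.95)])
        net = build_network(table, "G1", NetworkConfig(seed=13))
        assert ("OTU_3", "OTU_6") in net.graph.edges
        assert net.graph.edges["OTU_3", "OTU_6"]["sign"] == "negative"

    def test_every_edge_satisfies_reporting_invariants(self):
        table, _, _ = _synthetic_table(3, planted=[(0, 1, 0.9), (4, 9, -0.9)])
        cfg = NetworkConfig(seed=3)
        net = build_network(table, "G1", cfg)
        for _, _, attrs in net.graph.edges(data=True):
            assert abs(attrs["score"]) >= cfg.threshold
            assert attrs["q"] <= cfg.alpha
        kept_pairs = set(map(frozenset, net.graph.edges))
        for t in net.edge_tests:
            if frozenset(t.pair) in kept_pairs:
                assert t.stable

    def test_determinism_same_seed(self):
        table, _, _ = _synthetic_table(21, planted=[(0, 1, 0.9)])
        cfg = NetworkConfig(seed=21)
        n1 = build_network(table, "G1", cfg)
        n2 = build_network(table, "G1", cfg)
        assert set(n1.graph.edges) == set(n2.graph.edges)
        for e in n1.graph.edges:
            assert n1.graph.edges[e]["q"] == n2.graph.edges[e]["q"]

    def test_symmetry_under_relabeling(self):
        table, _, _ = _synthetic_table(5, n_taxa=10, planted=[(0, 1, 0.95)])
        cfg = NetworkConfig(seed=5)
        net = build_network(table, "G1", cfg)
        # reverse taxon order (relabels rows, same data)
        rev = table.subset(otus=list(reversed(table.otu_ids)))
        net_rev = build_network(rev, "G1", cfg)
        assert set(map(frozenset, net.graph.edges)) == set(
            map(frozenset, net_rev.graph.edges)
        )

    def test_no_candidates_empty_network(self, caplog):
        table, _, _ = _synthetic_table(2, n_taxa=5, n_samples=40)
        with caplog.at_level("WARNING"):
            net = build_network(table, "G1", NetworkConfig(seed=2))
        assert net.n_nodes == 0
        assert net.edge_tests == []

    def test_node_attributes(self):
        table, _, _ = _synthetic_table(7, planted=[(0, 1, 0.95)])
        net = build_network(table, "G1", NetworkConfig(seed=7))
        attrs = net.graph.nodes["OTU_1"]
        assert attrs["node_class"] == "taxon"
        assert attrs["genus"] == "Genus_1"
        assert 0 < attrs["mean_relabund"] < 1

    def test_small_n_uses_exact_enumeration(self):
        # 5 samples -> exact null; pipeline still runs deterministically
        table, _, _ = _synthetic_table(31, n_taxa=6, n_samples=5)
        cfg = NetworkConfig(seed=31, n_bootstraps=200)
        n1 = build_network(table, "G1", cfg)
        n2 = build_network(table, "G1", cfg)
        assert set(n1.graph.edges) == set(n2.graph.edges)


class TestBuildMetadataNetwork:
    def test_metadata_edge_recovered(self):
        spec = SyntheticSpec(
            n_taxa=20, n_groups=1, n_replicates=40, depth=100_000, seed=17,
            metadata_spec=[("AP", 0, 0.95, 20.0, 4.0)],
        )
        table, metadata, _ = generate_dataset(spec)
        net = build_metadata_network(table, metadata, "G1", NetworkConfig(seed=17))
        assert ("OTU_1", "AP") in net.graph.edges or ("AP", "OTU_1") in net.graph.edges
        assert net.graph.nodes["AP"]["node_class"] == "metadata"

    def test_constant_metadata_skipped(self, caplog):
        spec = SyntheticSpec(
            n_taxa=10, n_groups=1, n_replicates=40, depth=50_000, seed=19,
            metadata_spec=[("EC", None, 0.0, 1.0, 0.0)],
        )
        table, metadata, _ = generate_dataset(spec)
        with caplog.at_level("WARNING"):
            net = build_metadata_network(table, metadata, "G1", NetworkConfig(seed=19))
        assert "EC" not in net.graph.nodes
        assert "constant" in caplog.text

    def test_no_metadata_reduces_to_plain_network(self):
        table, _, _ = _synthetic_table(7, planted=[(0, 1, 0.95)])
        empty_meta = SoilMetadata(
            data=pd.DataFrame(index=table.sample_ids)
        )
        cfg = NetworkConfig(seed=7)
        plain = build_network(table, "G1", cfg)
        withmeta = build_metadata_network(table, empty_meta, "G1", cfg)
        assert set(plain.graph.edges) == set(withmeta.graph.edges)
        for e in plain.graph.edges:
            assert plain.graph.edges[e]["q"] == withmeta.graph.edges[e]["q"]
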