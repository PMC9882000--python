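import math

import numpy as np
import pytest
import scipy.stats

import hetpath as hp
from hetpath.null_model import NullStats


def stats_row(N, n, s, s2):
    return {"n_dwpcs": N, "n_nonzero_dwpcs": n, "sum": s, "sum_of_squares": s2}


class TestDegreeGroupKey:
    def test_toy_source_degree(self, compound_gene):
        mp = compound_gene.metagraph.metapath_from_abbreviation("CbG")
        assert hp.degree_group_key(compound_gene, mp, "c1", "g2") == (2, 2)
        assert hp.degree_group_key(compound_gene, mp, "c2", "g3") == (1, 0)

    def test_key_swaps_under_reversal(self, compound_gene):
        mp = compound_gene.metagraph.metapath_from_abbreviation("CbG")
        d = hp.degree_group_key(compound_gene, mp, "c1", "g2")
        d_rev = hp.degree_group_key(compound_gene, hp.reverse(mp), "g2", "c1")
        assert d_rev == (d[1], d[0])

    def test_wrong_metanode_raises(self, compound_gene):
        mp = compound_gene.metagraph.metapath_from_abbreviation("CbG")
        with pytest.raises(KeyError):
            hp.degree_group_key(compound_gene, mp, "g1", "g2")


class TestAccumulateAndMerge:
    def test_all_zero_matrix(self):
        stats = hp.accumulate_null_stats(
            NullStats("AxB"), np.zeros((2, 2)), np.array([1, 1]), np.array([1, 1])
        )
        row = stats.group(1, 1)
        assert row["n_dwpcs"] == 4
        assert row["n_nonzero_dwpcs"] == 0
        assert row["sum"] == 0
        assert row["n_perms"] == 1

    def test_hand_accumulation(self):
        matrix = np.array([[0, 0.5], [0.25, 0.25]])
        stats = hp.accumulate_null_stats(
            NullStats("AxB"), matrix, np.array([1, 1]), np.array([1, 1])
        )
        row = stats.group(1, 1)
        assert row["n_dwpcs"] == 4
        assert row["n_nonzero_dwpcs"] == 3
        assert row["sum"] == 1.0
        assert row["sum_of_squares"] == 0.375

    def test_group_sizes_sum_to_matrix_size(self):
        rng = np.random.default_rng(0)
        matrix = rng.random((5, 7))
        d_s = rng.integers(0, 3, size=5)
        d_t = rng.integers(0, 3, size=7)
        stats = hp.accumulate_null_stats(NullStats("AxB"), matrix, d_s, d_t)
        assert stats.table["n_dwpcs"].sum() == 35

    def test_merge_identity_commutativity_additivity(self):
        rng = np.random.default_rng(1)
        m1, m2 = rng.random((3, 3)), rng.random((3, 3))
        d = np.array([0, 1, 1])
        a = hp.accumulate_null_stats(NullStats("AxB"), m1, d, d)
        b = hp.accumulate_null_stats(NullStats("AxB"), m2, d, d)
        empty = NullStats("AxB")
        assert hp.merge_stats(a, empty).table.equals(a.table)
        ab = hp.merge_stats(a, b)
        ba = hp.merge_stats(b, a)
        assert ab.table.equals(ba.table)
        joint = hp.accumulate_null_stats(a, m2, d, d)
        np.testing.assert_allclose(ab.table.to_numpy(), joint.table.to_numpy())

    def test_merge_different_metapaths_rejected(self):
        with pytest.raises(ValueError, match="metapath"):
            hp.merge_stats(NullStats("AxB"), NullStats("AyB"))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hp.accumulate_null_stats(
                NullStats("AxB"), np.zeros((2, 2)), np.array([1]), np.array([1, 1])
            )


class TestGammaHurdleFit:
    def test_worked_moments_example(self):
        """N=6, n=3, sum=6, sum_sq=14: lambda 0.5, mean 2, variance 1,
        alpha 4, beta 2 under method of moments with Bessel's correction."""
        params = hp.fit_gamma_hurdle(stats_row(6, 3, 6, 14))
        assert params.lam == pytest.approx(0.5)
        assert params.alpha == pytest.approx(4.0)
        assert params.beta == pytest.approx(2.0)

    def test_single_nonzero_falls_back(self):
        assert hp.fit_gamma_hurdle(stats_row(5, 1, 2.0, 4.0)) is None

    def test_zero_variance_falls_back(self):
        assert hp.fit_gamma_hurdle(stats_row(10, 4, 0.8, 0.16)) is None

    def test_empty_falls_back(self):
        assert hp.fit_gamma_hurdle(stats_row(0, 0, 0, 0)) is None

    def test_parameter_recovery_from_draws(self):
        """Refit on 1e5 seeded gamma-hurdle draws recovers each parameter
        within 5%."""
        rng = np.random.default_rng(2024)
        lam, alpha, beta = 0.6, 3.0, 2.0
        n = 100_000
        nonzero = rng.random(n) < lam
        x = rng.gamma(alpha, 1 / beta, size=int(nonzero.sum()))
        params = hp.fit_gamma_hurdle(
            stats_row(n, len(x), float(x.sum()), float((x**2).sum()))
        )
        assert params.lam == pytest.approx(lam, rel=0.05)
        assert params.alpha == pytest.approx(alpha, rel=0.05)
        assert params.beta == pytest.approx(beta, rel=0.05)


class TestGammaHurdlePValue:
    def test_zero_observation_covers_whole_support(self):
        params = hp.GammaHurdleParams(0.5, 1.0, 2.0)
        assert hp.gamma_hurdle_pvalue(0.0, params) == 1.0

    def test_exponential_closed_form(self):
        """With alpha = 1 the gamma tail is exp(-beta t), so p = lam e^-2."""
        params = hp.GammaHurdleParams(0.5, 1.0, 2.0)
        assert hp.gamma_hurdle_pvalue(1.0, params) == pytest.approx(
            0.5 * math.exp(-2), rel=1e-9
        )

    def test_vanishes_at_infinity(self):
        params = hp.GammaHurdleParams(0.8, 2.0, 1.0)
        assert hp.gamma_hurdle_pvalue(1e6, params) < 1e-300

    def test_strictly_decreasing_in_t(self):
        params = hp.GammaHurdleParams(0.7, 2.5, 1.5)
        ts = np.linspace(0.01, 20, 200)
        ps = [hp.gamma_hurdle_pvalue(t, params) for t in ts]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            hp.GammaHurdleParams(1.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            hp.GammaHurdleParams(0.5, -1.0, 1.0)


class TestEmpiricalPValue:
    def test_zero_observation_gives_one(self):
        assert hp.empirical_pvalue(0.0, stats_row(400, 7, 2.0, 1.0)) == 1.0

    def test_all_zero_null_gives_zero(self):
        assert hp.empirical_pvalue(0.3, stats_row(400, 0, 0.0, 0.0)) == 0.0

    def test_degenerate_nonzero_null(self):
        row = stats_row(10, 4, 0.8, 0.16)  # all nonzero nulls equal 0.2
        assert hp.empirical_pvalue(0.2, row) == pytest.approx(0.4)
        assert hp.empirical_pvalue(0.25, row) == 0.0


class TestDwpcPValue:
    def test_gamma_path_matches_direct_computation(self):
        row = stats_row(6, 3, 6, 14)
        sig = hp.dwpc_pvalue(1.5, row)
        assert sig.method == "gamma-hurdle"
        params = hp.fit_gamma_hurdle(row)
        assert sig.p_value == pytest.approx(hp.gamma_hurdle_pvalue(1.5, params))
        assert sig.nonzero_mean == pytest.approx(2.0)
        assert sig.nonzero_sd == pytest.approx(1.0)

    def test_fallback_method_recorded(self):
        sig = hp.dwpc_pvalue(0.5, stats_row(5, 1, 2.0, 4.0))
        assert sig.method == "empirical"

    def test_p_in_unit_interval_under_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            N = int(rng.integers(1, 50))
            n = int(rng.integers(0, N + 1))
            x = rng.random(n) * 3
            row = stats_row(N, n, float(x.sum()), float((x**2).sum()))
            t = float(rng.random() * 4)
            p = hp.dwpc_pvalue(t, row).p_value
            assert 0.0 <= p <= 1.0


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        mg = hp.hetionet_metagraph()
        # Disease..Pathway has 3 metapaths of length 2
        assert hp.bonferroni_adjust(0.02, mg, "D", "PW", 2) == pytest.approx(0.06)
        assert hp.bonferroni_adjust(0.5, mg, "D", "PW", 2) == 1.0

    def test_published_factor_of_three(self):
        """A Disease-Pathway p-value of 5.9% at length 2 triples to 17.7%
        (the metapath multiplicity is 3)."""
        mg = hp.hetionet_metagraph()
        adjusted = hp.bonferroni_adjust(0.059, mg, "D", "PW", 2)
        assert adjusted == pytest.approx(3 * 0.059)

    def test_no_metapaths_raises(self):
        mg = hp.hetionet_metagraph()
        with pytest.raises(ValueError):
            hp.bonferroni_adjust(0.05, mg, "D", "PW", 1)

    def test_adjusted_at_least_raw(self, random_store):
        mg = random_store(1).metagraph
        mps = hp.enumerate_metapaths(mg, 2)
        for mp in mps:
            adj = hp.bonferroni_adjust(0.01, mg, mp.source, mp.target, mp.length)
            assert adj >= 0.01


class TestNullCatalog:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        stats = hp.accumulate_null_stats(
            NullStats("AxBxA"),
            rng.random((4, 4)),
            np.array([1, 1, 2, 2]),
            np.array([1, 2, 2, 3]),
        )
        catalog = hp.NullCatalog(w=0.5, n_permutations=1)
        catalog.add(stats)
        catalog.save(tmp_path / "nulls")
        loaded = hp.NullCatalog.load(tmp_path / "nulls", None, w=0.5)
        assert loaded.metapath_abbreviations() == ["AxBxA"]
        a = stats.table.sort_index()
        b = loaded._stats["AxBxA"].table.sort_index()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_null_calibration_uniform_pvalues(self):
        """Hold one of 50 permutations out as observed: gamma tail
        probabilities of its nonzero DWPCs against the other 49 are
        approximately uniform (KS < 0.1 with >= 2,000 evaluable pairs)."""
        from conftest import small_bipartite_spec

        store = hp.make_fixture(small_bipartite_spec(7, n_a=50, n_b=50, density=0.2))
        mp = store.metagraph.metapath_from_abbreviation("AxBxA")
        perms = list(hp.generate_permutations(store, 50, base_seed=100))
        held, rest = perms[0], perms[1:]
        stats = NullStats(mp.abbreviation)
        for p in rest:
            matrix = hp.dwpc_matrix(p, mp, 0.5).matrix
            src_deg, _ = p.step_degrees(mp.steps[0])
            _, tgt_deg = p.step_degrees(mp.steps[-1])
            stats = hp.accumulate_null_stats(stats, matrix, src_deg, tgt_deg)
        observed = hp.dwpc_matrix(held, mp, 0.5).matrix
        src_deg, _ = held.step_degrees(mp.steps[0])
        _, tgt_deg = held.step_degrees(mp.steps[-1])
        tail_probs = []
        for i in range(observed.shape[0]):
            for j in range(observed.shape[1]):
                t = observed[i, j]
                if t <= 0:
                    continue
                params = hp.fit_gamma_hurdle(stats.group(src_deg[i], tgt_deg[j]))
                if params is None:
                    continue
                tail_probs.append(
                    hp.gamma_hurdle_pvalue(t, params) / params.lam
                )
        assert len(tail_probs) >= 2000
        ks = scipy.stats.kstest(tail_probs, "uniform").statistic
        assert ks < 0.1
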