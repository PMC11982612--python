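"""Binned landscapes, KL divergence, randomization and bootstrap tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import xover as xo
from xover.errors import InfiniteKLError, ValidationError, XoverError
from xover.landscape import bootstrap_kl_to_flat

from conftest import simulate_called


class TestBinning:
    def test_boundary_conventions(self):
        d = xo.bin_relative_positions([0.05, 0.05, 0.95, 1.0])
        assert d.counts.tolist() == [2, 0, 0, 0, 0, 0, 0, 0, 0, 2]

    def test_exact_bin_edge_goes_right(self):
        d = xo.bin_relative_positions([0.1])
        assert d.counts[1] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(XoverError):
            xo.bin_relative_positions([1.2])

    def test_uniform_positions_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        d = xo.bin_relative_positions(rng.random(10_000))
        sd = math.sqrt(10_000 * 0.1 * 0.9)
        assert np.all(np.abs(d.counts - 1_000) < 4 * sd)


class TestKLDivergence:
    def test_identical_distributions_vanish(self):
        p = xo.BinnedDistribution(np.array([3, 1, 4, 1, 5.0]))
        assert xo.kl_divergence(p, p) == 0.0

    def test_point_mass_vs_flat_is_log_bins(self):
        p = np.zeros(10)
        p[0] = 1.0
        assert xo.kl_divergence(p, np.full(10, 0.1)) == \
            pytest.approx(math.log(10))

    def test_two_bin_closed_form(self):
        assert xo.kl_divergence([0.2, 0.8], [0.5, 0.5]) == \
            pytest.approx(0.1927, abs=5e-5)

    def test_occupied_p_empty_q_raises_with_bin_report(self):
        with pytest.raises(InfiniteKLError) as err:
            xo.kl_divergence([0.5, 0.5, 0.0], [0.5, 0.0, 0.5])
        assert err.value.bins == [1]

    def test_pseudocount_option_resolves_empty_bins(self):
        p = xo.BinnedDistribution(np.array([5.0, 5, 0]))
        q = xo.BinnedDistribution(np.array([5.0, 0, 5]))
        assert np.isfinite(xo.kl_divergence(p, q.with_pseudocount()))

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=12),
           st.data())
    def test_nonnegative_and_zero_only_at_equality(self, counts, data):
        if sum(counts) == 0:
            counts[0] = 1.0
        p = np.asarray(counts) / sum(counts)
        q = np.asarray(data.draw(st.lists(
            st.floats(0.01, 10.0), min_size=len(counts),
            max_size=len(counts))))
        q = q / q.sum()
        kl = xo.kl_divergence(p, q)
        assert kl >= -1e-15
        if np.allclose(p, q, atol=1e-15):
            assert kl == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_probabilities_undefined(self):
        with pytest.raises(ValidationError):
            xo.BinnedDistribution(np.zeros(10)).probabilities()


class TestKLToFlat:
    def test_equal_bin_counts_give_zero(self):
        pos = np.concatenate([np.full(5, k / 10 + 0.05) for k in range(10)])
        assert xo.kl_to_flat(pos) == pytest.approx(0.0)

    def test_single_bin_concentration_gives_log_ten(self):
        assert xo.kl_to_flat(np.full(100, 0.03)) == \
            pytest.approx(math.log(10))

    def test_distal_preset_diverges_more_than_flat(self):
        wins = 0
        n_rep = 30
        for rep in range(n_rep):
            kls = {}
            for preset in ("flat", "distal"):
                mm, gm, ev, _ = simulate_called(
                    300, preset=preset, seed=3000 + rep)
                kls[preset] = xo.kl_to_flat(xo.relative_positions(ev, mm))
            wins += kls["distal"] > kls["flat"]
        assert wins >= int(0.95 * n_rep)


class TestFlatnessPValue:
    def test_zero_kl_has_pvalue_one(self):
        pos = np.concatenate([np.full(3, k / 10 + 0.05) for k in range(10)])
        res = xo.flatness_pvalue(pos, 200, seed=0)
        assert res.kl == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_extreme_concentration_beats_every_randomization(self):
        res = xo.flatness_pvalue(np.full(500, 0.03), 1_000, seed=1)
        assert res.p_value <= 1 / 1_000
        assert res.p_value < 1e-3

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        pos = rng.random(400)
        a = xo.flatness_pvalue(pos, 500, seed=9)
        b = xo.flatness_pvalue(pos, 500, seed=9)
        assert a.p_value == b.p_value and a.kl == b.kl

    def test_null_kl_shrinks_with_more_crossovers(self):
        # plug-in KL bias ~ (bins-1)/2N: medians must order by N
        rng = np.random.default_rng(6)
        med = {}
        for n in (500, 5_000):
            kls = [xo.kl_to_flat(rng.random(n)) for _ in range(100)]
            med[n] = np.median(kls)
        assert med[5_000] < med[500]


class TestBootstrap:
    def test_constant_statistic_is_degenerate(self, flat_population):
        mm, gm, events, _ = flat_population
        vals = xo.bootstrap_statistic(events, gm.individuals,
                                      lambda ev, ids: 7.5,
                                      n_bootstraps=50, seed=0)
        assert np.all(vals == 7.5)

    def test_bootstrap_se_of_mean_matches_formula(self, flat_population):
        mm, gm, events, _ = flat_population
        n = gm.n_individuals
        per_ind = events.groupby("individual").size() \
            .reindex(gm.individuals, fill_value=0)
        vals = xo.bootstrap_statistic(
            events, gm.individuals, lambda ev, ids: len(ev) / n,
            n_bootstraps=400, seed=1)
        se = per_ind.std(ddof=1) / math.sqrt(n)
        assert abs(vals.std(ddof=1) - se) / se < 0.2

    def test_same_seed_reproduces_distribution(self, flat_population):
        mm, gm, events, _ = flat_population
        counts = xo.individual_bin_counts(events, mm, gm.individuals)
        a = bootstrap_kl_to_flat(counts, 300, seed=2)
        b = bootstrap_kl_to_flat(counts, 300, seed=2)
        np.testing.assert_array_equal(a, b)


class TestOrderingTest:
    def test_identical_data_share_a_letter(self, flat_population):
        mm, gm, events, _ = flat_population
        counts = xo.individual_bin_counts(events, mm, gm.individuals)
        res = xo.ordering_test([("one", counts), ("two", counts)],
                               n_bootstraps=600, seed=3)
        assert res.letters["one"] == res.letters["two"]
        raw = res.pairs["raw_p"].iloc[0]
        assert 0.3 < raw < 0.7  # paired bootstrap under exact ties

    def test_three_populations_with_monotone_divergence(self):
        mid = ((0.0, 0.0), (0.25, 0.38), (0.5, 0.5), (0.75, 0.62),
               (1.0, 1.0))
        pops = []
        for name, preset_anchors, seed in [
                ("strong", xo.MAREY_PRESETS["distal"], 31),
                ("mild", mid, 32), ("flat", xo.MAREY_PRESETS["flat"], 33)]:
            chroms = tuple(xo.ChromosomeModel(f"chr{i:02d}", 25e6, 1.0,
                                              preset_anchors)
                           for i in range(10))
            mm = xo.uniform_marker_map(chroms, n_intervals=40)
            gm, _ = xo.simulate_population(
                xo.SimulationConfig(chroms, 400, seed=seed), mm)
            ev = xo.call_crossovers(gm, mm)
            pops.append((name, xo.individual_bin_counts(
                ev, mm, gm.individuals)))
        res = xo.ordering_test(pops, n_bootstraps=800, seed=34)
        assert res.statistics["strong"] > res.statistics["mild"] > \
            res.statistics["flat"]
        assert res.letters["strong"] == "a"
        assert res.letters["mild"] == "b"
        assert res.letters["flat"] == "c"


class TestPairwiseKL:
    def test_same_data_has_zero_point_estimate(self, flat_population):
        mm, gm, events, _ = flat_population
        counts = xo.individual_bin_counts(events, mm, gm.individuals)
        res = xo.pairwise_landscape_kl(counts, counts, 200, seed=4)
        assert res.kl == 0.0

    def test_kl_is_asymmetric_between_different_landscapes(self):
        mm_f, gm_f, ev_f, _ = simulate_called(300, "flat", seed=41)
        mm_d, gm_d, ev_d, _ = simulate_called(300, "distal", seed=42)
        cf = xo.individual_bin_counts(ev_f, mm_f, gm_f.individuals)
        cd = xo.individual_bin_counts(ev_d, mm_d, gm_d.individuals)
        ab = xo.pairwise_landscape_kl(cf, cd, 100, seed=5)
        ba = xo.pairwise_landscape_kl(cd, cf, 100, seed=5)
        assert ab.kl != ba.kl
        assert ab.ci[0] <= ab.ci[1]

    def test_ci_covers_typical_between_replicate_divergence(self):
        # the percentile-bootstrap CI of KL(A, B) should usually cover
        # the central sampling divergence between two replicates of the
        # same model (the CI sits high: resampling doubles the noise of
        # the plug-in statistic, so only central coverage is expected)
        def counts(seed):
            mm, gm, ev, _ = simulate_called(300, seed=seed)
            return xo.individual_bin_counts(ev, mm, gm.individuals)

        fresh = [xo.kl_divergence(
            xo.BinnedDistribution(counts(5000 + 2 * t).sum(axis=0)),
            xo.BinnedDistribution(counts(5001 + 2 * t).sum(axis=0)))
            for t in range(20)]
        central = np.median(fresh)
        n_trials = 20
        covered = 0
        for trial in range(n_trials):
            a = counts(5100 + 2 * trial)
            b = counts(5101 + 2 * trial)
            res = xo.pairwise_landscape_kl(a, b, 300, seed=600 + trial)
            covered += res.ci[0] <= central <= res.ci[1]
        assert covered >= int(0.8 * n_trials)
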