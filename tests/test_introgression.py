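"""ABBA-BABA site patterns, D, block jackknife and gamma estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodisc import core_io, msc_sim
from phylodisc.core_io import Alignment
from phylodisc.introgression import (GammaEstimate, InsufficientDataError,
                                     PatternCounts, UndefinedGammaError,
                                     abba_baba, block_jackknife,
                                     count_site_patterns, d_statistic,
                                     estimate_gamma)
from phylodisc.msc_sim import SubstModel, simulate_alignment, simulate_gene_trees

GROUPS = ({"P1"}, {"P2"}, {"P3"}, {"O"})


def _aln(cols: list[str]) -> Alignment:
    names = ["P1", "P2", "P3", "O"]
    return Alignment.from_sequences(
        [(n, "".join(c[i] for c in cols)) for i, n in enumerate(names)])


class TestPatternCounts:
    def test_abba(self):
        c = count_site_patterns(_aln(["AGGA"]), *GROUPS)
        assert (c.n_abba, c.n_baba, c.n_bbaa) == (1, 0, 0)

    def test_baba(self):
        c = count_site_patterns(_aln(["GAGA"]), *GROUPS)
        assert (c.n_abba, c.n_baba, c.n_bbaa) == (0, 1, 0)

    def test_bbaa(self):
        c = count_site_patterns(_aln(["GGAA"]), *GROUPS)
        assert c.n_bbaa == 1

    def test_monomorphic_skipped(self):
        c = count_site_patterns(_aln(["AAAA"]), *GROUPS)
        assert c.n_considered == 0 and c.n_skipped == 1

    def test_multiallelic_and_missing_skipped(self):
        c = count_site_patterns(_aln(["ACGT", "A-GA"]), *GROUPS)
        assert c.n_considered == 0 and c.n_skipped == 2

    def test_other_biallelic_counts_considered_only(self):
        c = count_site_patterns(_aln(["GAAA"]), *GROUPS)  # only P1 derived
        assert c.n_considered == 1
        assert c.n_abba + c.n_baba + c.n_bbaa == 0

    def test_majority_collapse_and_ties(self):
        aln = Alignment.from_sequences([
            ("a1", "AA"), ("a2", "AG"), ("a3", "AA"),
            ("b", "GG"), ("c", "GG"), ("o", "AA")])
        c = count_site_patterns(aln, {"a1", "a2", "a3"}, {"b"}, {"c"}, {"o"})
        # both columns collapse P1 to A (majority 2:1) -> ABBA
        assert c.n_abba == 2

    def test_even_group_tie_skips(self):
        aln = Alignment.from_sequences([
            ("a1", "A"), ("a2", "G"), ("b", "G"), ("c", "G"), ("o", "A")])
        c = count_site_patterns(aln, {"a1", "a2"}, {"b"}, {"c"}, {"o"})
        assert c.n_considered == 0

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            count_site_patterns(_aln(["AGGA"]), {"P1"}, {"P1"}, {"P3"}, {"O"})


class TestDStatistic:
    def test_arithmetic(self):
        assert d_statistic(PatternCounts(3, 1, 0, 4, 0)) == 0.5

    def test_symmetry(self):
        for k in (1, 5, 100):
            assert d_statistic(PatternCounts(k, k, 0, 2 * k, 0)) == 0.0

    def test_no_informative_sites(self):
        assert d_statistic(PatternCounts(0, 0, 5, 5, 0)) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry_under_p1_p2_swap(self, seed):
        """Swapping P1 and P2 negates D exactly."""
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 4, size=(4, 400)).astype(np.uint8)
        aln = Alignment(["P1", "P2", "P3", "O"], data)
        d12 = d_statistic(count_site_patterns(aln, *GROUPS))
        d21 = d_statistic(count_site_patterns(
            aln, {"P2"}, {"P1"}, {"P3"}, {"O"}))
        assert d12 == pytest.approx(-d21)


class TestBlockJackknife:
    def _sim_alignment(self, gamma, n_loci, seed, n_sites=500):
        if gamma is None:
            net = msc_sim.make_scenario("ils_only")
        else:
            net = msc_sim.make_scenario("hybrid", gamma=gamma,
                                        parental_branch=3.0)
        gts = simulate_gene_trees(net, n_loci, seed)
        model = SubstModel()
        alns = [simulate_alignment(gt, model, n_sites, seed * 100000 + i)
                for i, gt in enumerate(gts)]
        return core_io.concatenate(alns)

    def test_se_zero_flagged_infinite(self):
        cols = ["AGGA", "GAGA"] * 2000  # perfectly balanced, D = 0
        aln = _aln(cols)
        se, z = block_jackknife(aln, GROUPS, block_size=400)
        assert se == 0.0 and math.isnan(z)

    def test_block_order_invariance(self, roles):
        aln = self._sim_alignment(None, 60, 17)
        se1, _ = block_jackknife(
            aln, (roles["p1"], roles["p2"], roles["p3"], roles["outgroup"]),
            block_size=1000)
        perm = np.concatenate([np.arange(15000, 30000),
                               np.arange(0, 15000)])
        aln2 = Alignment(aln.names, aln.data[:, perm])
        se2, _ = block_jackknife(
            aln2, (roles["p1"], roles["p2"], roles["p3"], roles["outgroup"]),
            block_size=1000)
        assert se1 == pytest.approx(se2)

    def test_too_few_blocks_rejected(self, roles):
        aln = self._sim_alignment(None, 4, 3)
        with pytest.raises(InsufficientDataError):
            block_jackknife(
                aln, (roles["p1"], roles["p2"], roles["p3"],
                      roles["outgroup"]), block_size=1000, min_blocks=10)

    def test_null_means_no_signal(self, roles):
        """Ten ILS-only replicates: D hovers near zero, |Z| modest."""
        zs, ds = [], []
        for rep in range(10):
            aln = self._sim_alignment(None, 80, 900 + rep)
            res = abba_baba(aln, roles["p1"], roles["p2"], roles["p3"],
                            roles["outgroup"])
            zs.append(res.z)
            ds.append(res.d)
        assert abs(np.mean(ds)) < 0.15
        assert np.mean(np.abs(zs) < 3) >= 0.8

    def test_gene_flow_gives_positive_signal(self, roles):
        aln = self._sim_alignment(0.3, 200, 55)
        res = abba_baba(aln, roles["p1"], roles["p2"], roles["p3"],
                        roles["outgroup"])
        assert res.d > 0.3 and res.z > 3

    def test_delete_m_mode_close_to_full(self, roles):
        aln = self._sim_alignment(0.3, 120, 66)
        g = (roles["p1"], roles["p2"], roles["p3"], roles["outgroup"])
        se_full, _ = block_jackknife(aln, g, block_size=500)
        se_sub, _ = block_jackknife(aln, g, block_size=500,
                                    n_replicates=60, seed=5)
        assert se_sub == pytest.approx(se_full, rel=0.6)


class TestGammaEstimate:
    def _trees(self, gamma, n_loci=800, seed=23, pb=3.0):
        net = msc_sim.make_scenario("hybrid", gamma=gamma,
                                    parental_branch=pb)
        return simulate_gene_trees(net, n_loci, seed)

    def test_all_parent1_gives_one(self, roles):
        gts = self._trees(1.0)
        est = estimate_gamma(gts, roles["hybrid"], roles["parent1"],
                             roles["parent2"], "OUT", n_boot=100)
        assert est.gamma_hat > 0.97

    def test_half_and_half(self, roles):
        gts = self._trees(0.5, n_loci=1500)
        est = estimate_gamma(gts, roles["hybrid"], roles["parent1"],
                             roles["parent2"], "OUT", n_boot=200)
        assert 0.45 <= est.gamma_hat <= 0.55

    def test_parent_swap_complements(self, roles):
        gts = self._trees(0.3)
        a = estimate_gamma(gts, roles["hybrid"], roles["parent1"],
                           roles["parent2"], "OUT", n_boot=50)
        b = estimate_gamma(gts, roles["hybrid"], roles["parent2"],
                           roles["parent1"], "OUT", n_boot=50)
        assert a.gamma_hat == pytest.approx(1 - b.gamma_hat)

    def test_monotone_in_true_gamma(self, roles):
        hats = []
        for g in (0.0, 0.25, 0.5, 0.75, 1.0):
            gts = self._trees(g, n_loci=600, seed=37)
            est = estimate_gamma(gts, roles["hybrid"], roles["parent1"],
                                 roles["parent2"], "OUT", n_boot=10)
            hats.append(est.gamma_hat)
        assert all(b >= a - 0.03 for a, b in zip(hats, hats[1:]))

    def test_ci_covers_estimate(self, roles):
        gts = self._trees(0.3, n_loci=500)
        est = estimate_gamma(gts, roles["hybrid"], roles["parent1"],
                             roles["parent2"], "OUT", n_boot=300, seed=8)
        assert est.ci_low <= est.gamma_hat <= est.ci_high
        assert est.votes_parent1 + est.votes_parent2 + est.abstentions == 500

    def test_disjointness_enforced(self, roles):
        gts = self._trees(0.5, n_loci=10)
        with pytest.raises(ValueError):
            estimate_gamma(gts, "B1", {"B1", "A1"}, {"B2"}, "OUT")
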