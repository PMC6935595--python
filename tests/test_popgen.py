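"""Diversity, neutrality, inbreeding and relatedness statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treesel import popgen
from treesel.popgen import (
    MISSING, SiteAlignment, classify_coding_sites, diversity_summary,
    fu_li_star, inbreeding_coefficient, neutrality_tests,
    nucleotide_diversity, pa_ps_ratio, pairwise_relatedness_ajk,
    polymorphic_percentage, region_summary, site_spectrum_counts, tajimas_d,
)

from .conftest import make_dataset
from . import oracles


def aln(rows, **kw):
    return SiteAlignment(gene_id="g", alleles=np.array(rows, dtype=np.int8), **kw)


class TestNucleotideDiversity:
    def test_single_site_two_alleles_balanced(self):
        # A,A,T,T: h = (4/3)(1 - 1/2) = 2/3 = 4 differing pairs of 6
        a = aln([[0], [0], [1], [1]])
        pi, acc = nucleotide_diversity(a)
        assert pi == pytest.approx(2.0 / 3.0, abs=1e-15)
        assert acc == 1.0

    def test_singleton_site_with_monomorphic_background(self):
        # one A,T,T,T site + 9 monomorphic sites: pi = 0.5 / 10
        rows = np.zeros((4, 10), dtype=np.int8)
        rows[0, 0] = 1
        pi, acc = nucleotide_diversity(aln(rows))
        assert acc == 10.0
        assert pi == pytest.approx(0.05, abs=1e-15)

    def test_monomorphic_alignment_is_zero(self):
        pi, _ = nucleotide_diversity(aln(np.zeros((6, 25), dtype=np.int8)))
        assert pi == 0.0

    def test_class_weights_select_sites(self):
        rows = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        a = aln(rows, w_syn=np.array([1.0, 0.0]), w_nonsyn=np.array([0.0, 1.0]))
        pi_syn, acc_syn = nucleotide_diversity(a, "syn")
        pi_nonsyn, _ = nucleotide_diversity(a, "nonsyn")
        assert acc_syn == 1.0
        assert pi_syn == pytest.approx(2.0 / 3.0)
        assert pi_nonsyn == pytest.approx(2.0 / 3.0)

    def test_empty_class_returns_nan(self):
        a = aln([[0], [1]], w_syn=np.array([0.0]), w_nonsyn=np.array([0.0]))
        pi, acc = nucleotide_diversity(a, "syn")
        assert np.isnan(pi) and acc == 0.0

    def test_matches_brute_force_on_random_alignments(self, rng):
        """Oracle equivalence: pi equals enumerated mean pairwise per-site
        difference on random alignments with missing data."""
        for _ in range(60):
            n = rng.integers(2, 11)
            L = rng.integers(1, 51)
            a = rng.integers(0, 3, size=(n, L)).astype(np.int8)
            a[rng.random(a.shape) < 0.2] = MISSING
            alignment = aln(a)
            pi, acc = nucleotide_diversity(alignment)
            expected = oracles.brute_force_pi(a)
            if np.isnan(expected):
                assert np.isnan(pi)
            else:
                assert pi == pytest.approx(expected, abs=1e-12)

    def test_class_additivity(self, rng):
        """Sum of class diversities weighted by accessible sites equals the
        all-sites diversity when weights partition every site."""
        a = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        w_syn = rng.uniform(0, 1, 30)
        w_nonsyn = (1 - w_syn) * rng.uniform(0, 1, 30)
        alignment = aln(a, w_syn=w_syn, w_nonsyn=w_nonsyn)
        total = 0.0
        for cls in ("syn", "nonsyn", "other"):
            pi, acc = nucleotide_diversity(alignment, cls)
            total += (pi * acc if acc else 0.0)
        pi_all, acc_all = nucleotide_diversity(alignment, "all")
        assert total == pytest.approx(pi_all * acc_all, rel=1e-12)

    def test_invariant_to_sample_and_site_permutation(self, rng, f1_alignment):
        base = diversity_summary(f1_alignment)
        perm = f1_alignment.alleles[rng.permutation(6)][:, rng.permutation(40)]
        shuffled = diversity_summary(aln(perm))
        assert shuffled.pi_all == pytest.approx(base.pi_all, abs=1e-15)
        assert (shuffled.S, shuffled.eta, shuffled.eta_s) == \
            (base.S, base.eta, base.eta_s)


class TestSiteSpectrum:
    @pytest.mark.parametrize("column,expected", [
        ([1, 0, 0, 0, 0, 0], (1, 1, 1)),        # counts (1,5)
        ([2, 1, 0, 0, 0, 0], (1, 2, 2)),        # counts (1,1,4)
        ([0, 0, 0, 0, 0, 0], (0, 0, 0)),        # monomorphic
        ([1, 1, 0, 0, 0, 0], (1, 1, 0)),        # doubleton: no singleton
    ])
    def test_column_contributions(self, column, expected):
        S, eta, eta_s, n_eff = site_spectrum_counts(aln(np.array([column]).T))
        assert (S, eta, eta_s) == expected
        assert n_eff == 6

    def test_missing_copies_reduce_n_eff(self):
        a = np.zeros((5, 3), dtype=np.int8)
        a[0, :] = MISSING
        a[1, 0] = 1
        S, eta, eta_s, n_eff = site_spectrum_counts(aln(a))
        assert (S, eta, eta_s, n_eff) == (1, 1, 1, 4)


class TestNeutralityTests:
    def test_undefined_when_no_segregating_sites(self):
        assert np.isnan(tajimas_d(10, 0, 0.0))
        assert all(np.isnan(v) for v in fu_li_star(10, 0, 0, 0.0))
        res = neutrality_tests(aln(np.zeros((6, 10), dtype=np.int8)))
        assert not res.defined

    def test_fixture_matches_exact_constant_oracle(self, f1_alignment):
        """Constant-by-constant agreement with exact-rational re-derivations."""
        S, eta, eta_s, n = site_spectrum_counts(f1_alignment)
        pi_sum = popgen._pi_sum(f1_alignment)
        d = tajimas_d(n, S, pi_sum)
        assert d == pytest.approx(oracles.tajimas_d_exact(n, S, pi_sum), abs=1e-12)
        dstar, fstar = fu_li_star(n, eta, eta_s, pi_sum)
        od, of = oracles.fu_li_star_exact(n, eta, eta_s, pi_sum)
        assert dstar == pytest.approx(od, abs=1e-6)
        assert fstar == pytest.approx(of, abs=1e-6)

    def test_excess_intermediate_frequencies_gives_positive_d(self):
        # all sites at 50/50: the bottleneck-like configuration
        a = np.zeros((10, 20), dtype=np.int8)
        a[:5, :10] = 1
        res = neutrality_tests(aln(a))
        assert res.tajima_d > 0

    def test_excess_singletons_gives_negative_statistics(self):
        a = np.zeros((10, 20), dtype=np.int8)
        for j in range(10):
            a[j % 10, j] = 1
        res = neutrality_tests(aln(a))
        assert res.tajima_d < 0
        assert res.fu_li_d_star < 0


class TestClassifyCodingSites:
    def test_fourfold_degenerate_third_position(self):
        w_syn, w_nonsyn = classify_coding_sites("GGG")
        assert w_syn[2] == 1.0 and w_nonsyn[2] == 0.0

    def test_methionine_first_position_fully_nonsynonymous(self):
        w_syn, _ = classify_coding_sites("ATG")
        assert w_syn[0] == 0.0

    def test_isoleucine_third_position_two_thirds(self):
        w_syn, w_nonsyn = classify_coding_sites("ATT")
        assert w_syn[2] == pytest.approx(2.0 / 3.0)
        assert w_nonsyn[2] == pytest.approx(1.0 / 3.0)

    def test_frame_offset_and_ambiguity(self):
        with pytest.warns(UserWarning):
            w_syn, _ = classify_coding_sites("ANNGGG", frame=0)
        assert np.isnan(w_syn[0]) and w_syn[5] == 1.0

    def test_weights_always_partition(self):
        w_syn, w_nonsyn = classify_coding_sites("ATGGATTTTAAACCCGGGTGA")
        ok = ~np.isnan(w_syn)
        assert np.allclose(w_syn[ok] + w_nonsyn[ok], 1.0)


class TestInbreedingAndRelatedness:
    def test_direction_of_f(self):
        # 10 sites at p = 0.5 (two balanced homozygotes anchor the frequency)
        G = np.column_stack([np.zeros(10), np.full(10, 2),
                             np.ones(10), np.ones(10)]).astype(np.int8)
        F = inbreeding_coefficient(G)
        assert F[2] < 0 and F[3] < 0     # always heterozygous
        assert F[0] > 0 and F[1] > 0     # always homozygous

    def test_hand_computed_three_individuals(self):
        # 2 sites, genotypes: ind1 (0,2), ind2 (1,1), ind3 (2,0)
        G = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        # p = 0.5, n = 6 copies at both sites: E_hom/site = 1 - 2*.25*(6/5) = 0.4
        F = inbreeding_coefficient(G)
        assert F[0] == pytest.approx((2 - 0.8) / (2 - 0.8))
        assert F[1] == pytest.approx((0 - 0.8) / (2 - 0.8))

    def test_single_site_formula_value(self):
        # M = 1, x_j = x_k = 2, p = 0.5 -> A_jk = 1*1/0.5 = 2
        G = np.array([[2, 2, 0, 0]], dtype=np.int8)
        res = pairwise_relatedness_ajk(G)
        assert res.ajk[0, 1] == pytest.approx(2.0)

    def test_duplicated_individual_tops_relatedness(self, rng):
        G = rng.binomial(2, 0.5, size=(400, 6)).astype(np.int8)
        G[:, 5] = G[:, 0]  # clone
        res = pairwise_relatedness_ajk(G)
        off = res.ajk.copy()
        np.fill_diagonal(off, -np.inf)
        assert np.unravel_index(np.argmax(off), off.shape) in [(0, 5), (5, 0)]
        assert off[0, 5] > 0.6

    def test_unrelated_pair_near_zero(self, rng):
        # frequencies are sample-estimated, so embed the pair in a panel
        # large enough that the -1/(n-1) plug-in bias is negligible
        G = rng.binomial(2, 0.5, size=(1000, 20)).astype(np.int8)
        res = pairwise_relatedness_ajk(G)
        assert abs(res.ajk[0, 1]) < 0.1

    def test_symmetry(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 5)).astype(np.int8)
        res = pairwise_relatedness_ajk(G)
        assert np.allclose(res.ajk, res.ajk.T, equal_nan=True)


class TestRegionSummary:
    def test_derived_ratio_and_percentage_fields(self):
        assert pa_ps_ratio(2.76, 8.97) == pytest.approx(0.308, abs=5e-4)
        assert polymorphic_percentage(20680, 25726) == pytest.approx(80.38, abs=0.01)

    def test_single_population_equals_overall(self, rng):
        G = rng.binomial(2, 0.4, size=(30, 8)).astype(np.int8)
        ds = make_dataset(G, ["p1"] * 8)
        table = region_summary(ds)
        assert table.loc["p1", "pi_all"] == pytest.approx(table.loc["All", "pi_all"])
        assert table.loc["p1", "tajima_d"] == pytest.approx(table.loc["All", "tajima_d"],
                                                            nan_ok=True)

    def test_undefined_neutrality_for_tiny_region(self, rng):
        G = rng.binomial(2, 0.4, size=(20, 5)).astype(np.int8)
        ds = make_dataset(G, ["big"] * 4 + ["tiny"])
        table = region_summary(ds)
        assert np.isnan(table.loc["tiny", "tajima_d"])  # 2 copies < 4

    def test_unmapped_population_raises(self, rng):
        G = rng.binomial(2, 0.4, size=(5, 4)).astype(np.int8)
        ds = make_dataset(G, ["p1", "p1", "p2", "p2"])
        with pytest.raises(ValueError, match="p2"):
            region_summary(ds, regions={"p1": "west"})

    def test_total_length_rescales_pi(self, rng):
        G = rng.binomial(2, 0.4, size=(40, 10)).astype(np.int8)
        ds = make_dataset(G, ["p1"] * 10)
        panel = region_summary(ds)
        scaled = region_summary(ds, total_length=4000.0)
        acc = panel.loc["All", "length_bp"]
        assert scaled.loc["All", "pi_all"] == pytest.approx(
            panel.loc["All", "pi_all"] * acc / 4000.0)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=4, max_value=30),
       st.integers(min_value=1, max_value=40))
def test_tajima_d_bounded_for_valid_inputs(n, S):
    """D is finite whenever S >= 1 and n >= 4, for any attainable pi_sum."""
    for pi_sum in (0.0, S / 2.0, float(S)):
        d = tajimas_d(n, S, pi_sum)
        assert np.isfinite(d)
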