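"""Diversity indices, founder-effect %r, Weir-Cockerham FST and composite LD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limadom import popgen
from limadom.fixtures import simulate_fixture_dataset

from conftest import make_matrix


class TestAlleleFrequencies:
    def test_two_samples_codes_0_and_2_give_half(self):
        gm = make_matrix([[0], [2]], ["MIW", "MIW"])
        assert popgen.allele_frequencies(gm, "MIW")[0] == 0.5

    def test_all_missing_locus_is_undefined(self):
        gm = make_matrix([[-1, 0], [-1, 2]], ["MIW", "MIW"])
        p = popgen.allele_frequencies(gm, "MIW")
        assert np.isnan(p[0]) and p[1] == 0.5

    def test_unknown_population_raises(self):
        gm = make_matrix([[0]], ["MIW"])
        with pytest.raises(ValueError, match="unknown"):
            popgen.allele_frequencies(gm, "XX")

    def test_planted_frequencies_recovered_within_binomial_error(self, rng):
        truth = np.array([0.1, 0.3, 0.5])
        gm = simulate_fixture_dataset({"MIW": truth}, {"MIW": 500}, rng=rng)
        est = popgen.allele_frequencies(gm, "MIW")
        se = np.sqrt(truth * (1 - truth) / (2 * 500))
        assert np.all(np.abs(est - truth) < 3 * se)


class TestDiversityPanel:
    def test_closed_forms_at_p_half(self):
        gm = make_matrix([[0], [2]], ["MIW", "MIW"])
        t = popgen.diversity_panel(gm, ["MIW"]).table.loc["MIW"]
        assert t.H_E == pytest.approx(0.5)
        assert t.N_E == pytest.approx(2.0)
        assert t.I == pytest.approx(np.log(2))
        assert t.N_A == 2.0

    def test_monomorphic_locus(self):
        gm = make_matrix([[0], [0]], ["MIW", "MIW"])
        t = popgen.diversity_panel(gm, ["MIW"]).table.loc["MIW"]
        assert t.H_E == 0.0 and t.N_A == 1.0 and t.I == 0.0
        assert np.isnan(t.F)  # undefined where H_E = 0

    def test_fully_homozygous_polymorphic_population_has_f_one(self, rng):
        # the autogamous pattern: H_O = 0 at polymorphic loci forces F = 1
        gm = simulate_fixture_dataset(
            {"MIW": rng.uniform(0.2, 0.8, 100)}, {"MIW": 40}, autogamous=True, rng=rng
        )
        t = popgen.diversity_panel(gm, ["MIW"]).table.loc["MIW"]
        assert t.H_O == 0.0
        assert t.F == pytest.approx(1.0)

    def test_he_symmetric_in_p(self):
        gm = make_matrix([[0], [0], [0], [2]], ["MIW"] * 4)   # p = 0.25
        gm2 = make_matrix([[2], [2], [2], [0]], ["MIW"] * 4)  # p = 0.75
        he1 = popgen.diversity_panel(gm, ["MIW"]).table.loc["MIW", "H_E"]
        he2 = popgen.diversity_panel(gm2, ["MIW"]).table.loc["MIW", "H_E"]
        assert he1 == pytest.approx(he2)

    def test_unbiased_option_scales_he(self):
        gm = make_matrix([[0], [2]], ["MIW", "MIW"])
        t = popgen.diversity_panel(gm, ["MIW"], unbiased=True).table.loc["MIW"]
        assert t.H_E == pytest.approx(0.5 * 4 / 3)  # 2n/(2n-1) with n=2


class TestPercentReduction:
    @pytest.mark.parametrize(
        "hew,hed,expected",
        [(0.278, 0.227, 18.34), (0.115, 0.079, 31.30), (0.3, 0.3, 0.0)],
    )
    def test_reported_reductions(self, hew, hed, expected):
        assert popgen.percent_reduction(hew, hed) == pytest.approx(expected, abs=0.02)

    def test_zero_wild_he_raises(self):
        with pytest.raises(ValueError):
            popgen.percent_reduction(0.0, 0.1)

    @given(a=st.floats(0.01, 0.5), b=st.floats(0.01, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_sign_under_swap(self, a, b):
        ra = popgen.percent_reduction(a, b)
        rb = popgen.percent_reduction(b, a)
        assert (ra > 0) == (rb < 0) or (ra == 0 and rb == 0)

    def test_per_locus_shares_sum_to_100(self, rng):
        gm = simulate_fixture_dataset(
            {"MIW": rng.uniform(0.05, 0.95, 200), "MID": rng.uniform(0.05, 0.95, 200)},
            {"MIW": 30, "MID": 30},
            rng=rng,
        )
        rep = popgen.per_locus_reduction(gm, "MIW", "MID")
        assert rep.share_positive + rep.share_negative + rep.share_zero == pytest.approx(100.0)


def _wc_theta_oracle(genos_a, genos_b):
    """Scalar W&C theta written directly from the variance-component formulas."""
    num = den = 0.0
    for j in range(len(genos_a[0])):
        ca = [g[j] for g in genos_a if g[j] >= 0]
        cb = [g[j] for g in genos_b if g[j] >= 0]
        na, nb = len(ca), len(cb)
        pa = sum(ca) / (2 * na)
        pb = sum(cb) / (2 * nb)
        ha = sum(1 for x in ca if x == 1) / na
        hb = sum(1 for x in cb if x == 1) / nb
        r = 2
        nbar = (na + nb) / r
        nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
        pbar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


class TestFst:
    def test_opposite_fixation_gives_one(self):
        gm = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2]], ["MIW", "MIW", "MID", "MID"])
        multi, per_locus = popgen.fst_weir_cockerham(gm, "MIW", "MID")
        assert multi == pytest.approx(1.0)
        np.testing.assert_allclose(per_locus, 1.0)

    def test_identical_counts_give_non_positive_theta(self):
        g = [[0, 1], [1, 2], [0, 1], [1, 2]]
        gm = make_matrix(g, ["MIW", "MIW", "MID", "MID"])
        multi, _ = popgen.fst_weir_cockerham(gm, "MIW", "MID")
        assert multi <= 1e-12

    def test_matches_independent_variance_component_oracle(self):
        genos_a = [[0, 1, 2], [1, 2, 2], [0, 0, 1], [2, 1, 0]]
        genos_b = [[2, 2, 0], [2, 1, 0], [1, 2, 0], [2, 2, 1]]
        gm = make_matrix(
            genos_a + genos_b, ["MIW"] * 4 + ["MID"] * 4
        )
        multi, _ = popgen.fst_weir_cockerham(gm, "MIW", "MID")
        assert multi == pytest.approx(_wc_theta_oracle(genos_a, genos_b))

    def test_random_split_of_one_population_gives_theta_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 400)
        gm = simulate_fixture_dataset({"X": p}, {"X": 200}, rng=rng)
        labels = np.array(["MIW"] * 100 + ["MID"] * 100)
        rng.shuffle(labels)
        gm.samples["population"] = labels
        multi, _ = popgen.fst_weir_cockerham(gm, "MIW", "MID")
        assert abs(multi) < 0.01

    def test_empty_population_raises(self):
        gm = make_matrix([[0], [2]], ["MIW", "MIW"])
        with pytest.raises(ValueError):
            popgen.fst_weir_cockerham(gm, "MIW", "MID")

    def test_nei_gst_agrees_on_strong_differentiation(self):
        gm = make_matrix([[0, 0], [0, 0], [2, 2], [2, 2]], ["MIW", "MIW", "MID", "MID"])
        multi, _ = popgen.fst_nei_gst(gm, "MIW", "MID")
        assert multi == pytest.approx(1.0)


class TestLd:
    def test_duplicated_locus_has_r2_one(self):
        gm = make_matrix([[0, 0], [1, 1], [2, 2], [0, 0]], ["MIW"] * 4)
        r2 = popgen.ld_r2_matrix(gm)
        assert r2[0, 1] == pytest.approx(1.0)

    def test_three_locus_mean_matches_hand_average(self):
        g = [[0, 0, 2], [1, 2, 0], [2, 1, 1], [0, 2, 2], [2, 0, 0]]
        gm = make_matrix(g, ["MIW"] * 5)
        r2 = popgen.ld_r2_matrix(gm)
        cols = np.array(g, float)
        expected = []
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            expected.append(np.corrcoef(cols[:, i], cols[:, j])[0, 1] ** 2)
        iu = np.triu_indices(3, 1)
        assert np.nanmean(r2[iu]) == pytest.approx(np.mean(expected))

    def test_planted_blocks(self, rng):
        from limadom.fixtures import simulate_ld_haplotypes

        gmA, _ = simulate_ld_haplotypes([(10, 1.0), (10, 1.0)], 40, rng=rng)
        r2 = popgen.ld_r2_matrix(gmA)
        within = r2[:10, :10][np.triu_indices(10, 1)]
        between = r2[:10, 10:]
        np.testing.assert_allclose(within, 1.0)
        assert np.nanmean(between) < 0.15

    def test_invariant_to_allele_coding_swap(self, rng):
        g = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        gm = make_matrix(g, ["MIW"] * 30)
        swapped = make_matrix(2 - g, ["MIW"] * 30)
        r2a = popgen.ld_r2_matrix(gm)
        r2b = popgen.ld_r2_matrix(swapped)
        np.testing.assert_allclose(r2a, r2b, atol=1e-12)

    def test_r2_in_unit_interval(self, rng):
        g = rng.integers(0, 3, size=(25, 8)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1
        r2 = popgen.ld_r2_matrix(make_matrix(g, ["MIW"] * 25))
        vals = r2[np.isfinite(r2)]
        assert np.all(vals >= -1e-12) and np.all(vals <= 1 + 1e-12)

    def test_absent_chromosome_raises(self):
        gm = make_matrix([[0, 2], [2, 0]], ["MIW"] * 2)
        with pytest.raises(ValueError, match="absent"):
            popgen.ld_r2_matrix(gm, chromosome="99")

    def test_chromosome_mean_table(self, rng):
        g = rng.integers(0, 3, size=(20, 12)).astype(np.int8)
        gm = make_matrix(
            g, ["MIW"] * 10 + ["MID"] * 10, chrom=["1"] * 6 + ["2"] * 6,
            pos=list(range(1, 7)) * 2,
        )
        table = popgen.chromosome_mean_r2(gm, {"Wild": ["MIW"], "Dom": ["MID"]})
        assert list(table.columns) == ["Wild", "Dom"]
        assert set(table.index) == {"1", "2"}
        assert ((table >= 0) & (table <= 1)).all().all()
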