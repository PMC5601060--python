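"""Selection scans: island-model FST null, outlier envelope, varLD scan."""

import numpy as np
import pandas as pd
import pytest

from limadom import scan as S
from limadom.fixtures import simulate_ld_haplotypes

from conftest import make_matrix


# 10,000 null loci put ~500 points in each of the 20 heterozygosity bins,
# enough to resolve the 0.5% tails of a 99% envelope
SMALL = S.FstNullConfig(
    n_datasets=10_000, demes_per_group=15, deme_size=100.0, migration_rate=0.025,
    calibration_loci=300, n_wild=30, n_dom=30,
)


@pytest.fixture(scope="module")
def small_cloud():
    return S.simulate_fst_null(0.25, SMALL, np.random.default_rng(11))


class TestIslandModelNull:
    def test_heavy_between_group_migration_removes_differentiation(self):
        counts = S._simulate_counts(
            S.FstNullConfig(demes_per_group=5, deme_size=100, migration_rate=0.5,
                            n_wild=30, n_dom=30),
            beta=0.5, n_loci=800, seed=21,
        )
        _, _, multi = S._null_he_fst(counts, 30, 30, True)
        assert abs(multi) < 0.05

    def test_rare_between_group_migration_approaches_fixation(self):
        counts = S._simulate_counts(SMALL, beta=2e-4, n_loci=300, seed=22)
        _, _, multi = S._null_he_fst(counts, 30, 30, True)
        assert multi > 0.8

    @pytest.mark.parametrize("nm,n_loci", [(1.0, 4000), (5.0, 12_000), (10.0, 16_000)])
    def test_collapsed_control_follows_island_model_closed_form(self, nm, n_loci):
        # beta = D/(2D-1) makes migration uniform over all demes: a plain
        # island model with d = 2D demes; FST ~ 1/(1 + 4Nm (d/(d-1))^2).
        # Locus counts grow with Nm because the multi-locus ratio estimator's
        # Monte-Carlo error is relatively larger when FST is small.
        D = 15
        d = 2 * D
        cfg = S.FstNullConfig(demes_per_group=D, deme_size=100.0,
                              migration_rate=nm / 100.0, n_wild=25, n_dom=25)
        counts = S._simulate_counts(cfg, beta=D / (2 * D - 1), n_loci=n_loci, seed=int(nm))
        _, _, multi = S._null_he_fst(counts, 25, 25, True)
        expected = 1.0 / (1.0 + 4 * nm * (d / (d - 1)) ** 2)
        assert multi == pytest.approx(expected, rel=0.10)

    def test_unattainable_target_raises_with_trace(self):
        with pytest.raises(RuntimeError, match="attainable"):
            S.simulate_fst_null(0.0005, SMALL, np.random.default_rng(1))

    def test_target_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            S.simulate_fst_null(1.5, SMALL)


class TestFlagOutliers:
    def test_null_drawn_data_flag_near_nominal_rate(self, small_cloud):
        counts = S._simulate_counts(SMALL, small_cloud.beta, 3000, 77)
        he, fst, _ = S._null_he_fst(counts, SMALL.n_wild, SMALL.n_dom, True)
        flags, _ = S.flag_outliers(he, fst, small_cloud, ci=0.99,
                                   rng=np.random.default_rng(5))
        rate = (flags != 0).mean()
        se = np.sqrt(0.01 * 0.99 / 3000)
        assert abs(rate - 0.01) < 3 * se

    def test_planted_extreme_locus_flagged_high(self, small_cloud):
        flags, _ = S.flag_outliers(
            np.array([0.3]), np.array([0.99]), small_cloud, ci=0.99
        )
        assert flags[0] == 1

    def test_ci_near_one_flags_nothing_inside_the_null_range(self, small_cloud):
        # ci -> 1 pushes the envelope to the null extremes: interior points
        # (away from the tie-dithered bin boundaries) can never flag
        lo, hi = np.quantile(small_cloud.fst, [0.02, 0.98])
        inner = (small_cloud.fst > lo) & (small_cloud.fst < hi)
        flags, _ = S.flag_outliers(
            small_cloud.he[inner][:500], small_cloud.fst[inner][:500],
            small_cloud, ci=0.9999,
        )
        assert (flags == 0).all()

    def test_envelope_bins_have_min_occupancy(self, small_cloud):
        _, env = S.flag_outliers(
            np.array([0.2]), np.array([0.1]), small_cloud, ci=0.99, min_bin_points=100
        )
        assert (env["n_null"] >= 100).all()


class TestVarldScan:
    def test_identical_inputs_score_exactly_zero(self, rng):
        gmA, _ = simulate_ld_haplotypes([(20, 0.7), (20, 0.7)], 40, rng=rng)
        res = S.varld_scan(gmA, gmA, window=10)
        assert (res.windows["raw"].dropna() == 0).all()

    def test_score_symmetric_in_populations(self, rng):
        gmA, gmB = simulate_ld_haplotypes(
            [(20, 1.0), (20, 1.0)], 40, divergence=0.5, diverged_blocks=(1,), rng=rng
        )
        r1 = S.varld_scan(gmA, gmB, window=10)
        r2 = S.varld_scan(gmB, gmA, window=10)
        np.testing.assert_allclose(r1.windows["raw"], r2.windows["raw"])

    def test_invariant_to_locus_order_within_a_window(self, rng):
        g = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        h = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
        perm = rng.permutation(12)
        gmA = make_matrix(g, ["W"] * 30)
        gmB = make_matrix(h, ["D"] * 30)
        gmA_p = make_matrix(g[:, perm], ["W"] * 30)
        gmB_p = make_matrix(h[:, perm], ["D"] * 30)
        raw = S.varld_scan(gmA, gmB, window=12).windows["raw"]
        raw_p = S.varld_scan(gmA_p, gmB_p, window=12).windows["raw"]
        np.testing.assert_allclose(raw, raw_p, atol=1e-9)

    def test_standardized_scores_have_zero_mean_unit_sd(self, rng):
        gmA, gmB = simulate_ld_haplotypes(
            [(30, 0.8), (30, 0.8), (30, 0.8)], 50, divergence=0.5,
            diverged_blocks=(2,), rng=rng,
        )
        res = S.varld_scan(gmA, gmB, window=15)
        std = res.windows["std"].dropna()
        assert std.mean() == pytest.approx(0.0, abs=1e-6)
        assert std.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_planted_divergent_block_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            gmA, gmB = simulate_ld_haplotypes(
                [(25, 1.0)] * 5, 60, divergence=0.9, diverged_blocks=(2,), rng=rng
            )
            res = S.varld_scan(gmA, gmB, window=25, step=5, top_fraction=0.05)
            block_lo, block_hi = 2 * 25, 3 * 25
            for _, reg in res.regions.iterrows():
                if reg.start_idx < block_hi and reg.end_idx > block_lo:
                    hits += 1
                    break
        assert hits >= 9

    def test_mismatched_loci_rejected(self, rng):
        gmA, _ = simulate_ld_haplotypes([(10, 0.5)], 20, rng=rng)
        gmB, _ = simulate_ld_haplotypes([(12, 0.5)], 20, rng=rng)
        with pytest.raises(ValueError, match="identical loci"):
            S.varld_scan(gmA, gmB, window=5)

    def test_permutation_p_values_valid_and_calibrated_under_null(self, rng):
        gmA, gmB = simulate_ld_haplotypes([(15, 0.6), (15, 0.6)], 40,
                                          divergence=0.0, rng=rng)
        res = S.varld_scan(gmA, gmB, window=15, step=15, n_perm=49, rng=rng)
        p = res.windows["perm_p"]
        assert ((p > 0) & (p <= 1)).all()
        assert (p < 0.05).mean() <= 0.5  # no true signal: small p should be rare


class TestGenesInRegions:
    def test_half_open_abutting_gene_not_counted(self):
        regions = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]})
        genes = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [200, 199], "end": [250, 210],
             "name": ["abutting", "overlapping"]}
        )
        out = S.genes_in_regions(regions, genes)
        assert out.loc[0, "n_genes"] == 1
        assert out.loc[0, "gene_names"] == "overlapping"

    def test_planted_counts(self):
        regions = pd.DataFrame({"chrom": ["2"], "start": [1000], "end": [2000]})
        genes = pd.DataFrame(
            {
                "chrom": ["2"] * 5,
                "start": [1100, 1500, 1990, 2000, 500],
                "end": [1200, 1600, 2100, 2200, 999],
                "name": list("abcde"),
            }
        )
        out = S.genes_in_regions(regions, genes)
        assert out.loc[0, "n_genes"] == 3
        assert out.loc[0, "gene_names"] == "a,b,c"

    def test_matches_quadratic_oracle_on_random_intervals(self, rng):
        def rand_intervals(n):
            starts = rng.integers(0, 10_000, n)
            lengths = rng.integers(1, 500, n)
            return pd.DataFrame(
                {
                    "chrom": rng.choice(["1", "2", "3"], n),
                    "start": starts,
                    "end": starts + lengths,
                    "name": [f"g{i}" for i in range(n)],
                }
            )

        regions = rand_intervals(100).drop(columns="name")
        genes = rand_intervals(1000)
        out = S.genes_in_regions(regions, genes)
        for i, r in regions.iterrows():
            expected = sum(
                1
                for _, g in genes.iterrows()
                if g.chrom == r.chrom and g.start < r.end and g.end > r.start
            )
            assert out.loc[i, "n_genes"] == expected
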