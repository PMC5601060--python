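"""ABC machinery: summary statistics, scenario choice, parameter posteriors."""

import numpy as np
import pandas as pd
import pytest

from limadom import abc as A
from limadom.coalescent import (
    _lay_out_genotypes,
    _matrix_from_genotypes,
    simulate_genotype_counts,
)
from limadom.demography import PriorSpec, SampleConfig, draw_parameters
from limadom.fixtures import simulate_fixture_dataset


@pytest.fixture(scope="module")
def small_table():
    """Shared 400-row reference table at 150 loci (both scenarios)."""
    return A.build_reference_table(PriorSpec(), SampleConfig(n_loci=150), 400, rng=2024)


def _planted_table(n_rows=400, shift=0.0, seed=0, n_shifted=6):
    """Synthetic table: scenario separated by a planted mean shift in several stats.

    ``shift = 0.1`` with noise sd 0.02 plants a 5-sd shift per affected
    statistic (several statistics shift so the unshifted noise dimensions do
    not dilute the standardized distance).
    """
    rng = np.random.default_rng(seed)
    half = n_rows // 2
    stats = rng.normal(0.25, 0.02, size=(n_rows, len(A.STAT_NAMES)))
    stats[half:, :n_shifted] += shift
    data = pd.DataFrame(stats, columns=list(A.STAT_NAMES))
    for name in A.ALL_PARAM_NAMES:
        lo, hi = PriorSpec().bounds[name]
        data[name] = rng.uniform(lo, hi, n_rows)
    data["scenario"] = [1] * half + [2] * half
    data = data[["scenario", *A.ALL_PARAM_NAMES, *A.STAT_NAMES]]
    return A.ReferenceTable(data=data, mads=A._stat_mads(data), seed=seed)


class TestSummaryStats:
    def test_counts_path_equals_genotype_path(self, rng):
        cfg = SampleConfig(n_loci=200)
        params = draw_parameters(PriorSpec(), 2, rng)
        derived, hom = simulate_genotype_counts(params, cfg, rng)
        fast = A.stats_from_counts(derived, hom, cfg)
        g = _lay_out_genotypes(7, derived, hom, cfg.diploid_counts, cfg.autogamous)
        full = A.summary_stats(_matrix_from_genotypes(g, cfg))
        np.testing.assert_allclose(fast, full, atol=1e-12)

    def test_admixture_coefficient_identities(self, rng):
        p_mid = rng.uniform(0.1, 0.9, 100)
        p_miiw = rng.uniform(0.1, 0.9, 100)
        assert A._admixture_coefficient(p_mid, p_miiw, p_mid) == pytest.approx(1.0)
        mid_point = (p_mid + p_miiw) / 2
        assert A._admixture_coefficient(p_mid, p_miiw, mid_point) == pytest.approx(0.5)
        assert A._admixture_coefficient(p_mid, p_mid, p_mid) == 0.5  # unidentifiable

    def test_admixture_recovered_from_planted_mixture(self, rng):
        n_loci = 2000
        p_mid = rng.uniform(0.1, 0.9, n_loci)
        p_miiw = rng.uniform(0.1, 0.9, n_loci)
        p_miid = np.clip(0.8 * p_mid + 0.2 * p_miiw + rng.normal(0, 0.02, n_loci), 0, 1)
        gm = simulate_fixture_dataset(
            {"MIW": rng.uniform(0.1, 0.9, n_loci), "MID": p_mid,
             "MIIW": p_miiw, "MIID": p_miid},
            {"MIW": 200, "MID": 200, "MIIW": 200, "MIID": 200},
            rng=rng,
        )
        stats = A.summary_stats(gm)
        assert stats[10] == pytest.approx(0.8, abs=0.05)

    def test_missing_population_raises(self, rng):
        gm = simulate_fixture_dataset(
            {"MIW": np.full(10, 0.5)}, {"MIW": 5}, rng=rng
        )
        with pytest.raises(ValueError):
            A.summary_stats(gm)


class TestReferenceTable:
    def test_row_counts_and_stat_ranges(self, small_table):
        scen = small_table.data["scenario"]
        assert (scen == 1).sum() == 200 and (scen == 2).sum() == 200
        he = small_table.data[[f"he_{p}" for p in A.POP_ORDER]].to_numpy()
        assert np.isfinite(small_table.stat_matrix()).all()
        assert (he >= 0).all() and (he <= 0.5).all()
        adm = small_table.data["adm"]
        assert ((adm >= 0) & (adm <= 1)).all()

    def test_bottleneck_severity_orders_he(self, small_table):
        d = small_table.data
        severe = d[d["N2b"] <= 500]["he_MID"]
        mild = d[d["N2b"] >= 4000]["he_MID"]
        assert severe.mean() < mild.mean()

    def test_save_load_round_trip(self, small_table, tmp_path):
        path = tmp_path / "ref.tsv"
        small_table.save(path)
        back = A.ReferenceTable.load(path)
        pd.testing.assert_frame_equal(
            small_table.data, back.data, check_exact=False, rtol=1e-12
        )
        assert back.config.n_loci == 150

    def test_reproducible_from_seed(self):
        cfg = SampleConfig(n_loci=40)
        t1 = A.build_reference_table(PriorSpec(), cfg, 100, rng=9)
        t2 = A.build_reference_table(PriorSpec(), cfg, 100, rng=9)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestDirectPosterior:
    def test_unique_closest_row_wins(self, small_table):
        obs = small_table.stat_matrix()[37]
        choice = A.direct_posterior(small_table, obs, n_closest=1)
        assert choice.probabilities[small_table.data["scenario"].iloc[37]] == 1.0

    def test_probabilities_sum_to_one_with_valid_cis(self, small_table):
        obs = small_table.stat_matrix().mean(axis=0)
        choice = A.direct_posterior(small_table, obs, n_closest=100)
        assert sum(choice.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
        for lo, hi in choice.intervals.values():
            assert 0 <= lo <= hi <= 1

    def test_label_shuffle_gives_even_odds(self):
        table = _planted_table(shift=0.0, seed=3)  # labels independent of stats
        obs = table.stat_matrix().mean(axis=0)
        choice = A.direct_posterior(table, obs, n_closest=200)
        assert choice.probabilities[1] == pytest.approx(0.5, abs=0.12)

    def test_planted_five_mad_shift_identified(self):
        table = _planted_table(shift=0.1, seed=4)  # shift = 5 x MAD of stat 0
        obs = table.stat_matrix()[table.data["scenario"] == 2].mean(axis=0)
        choice = A.direct_posterior(table, obs, n_closest=100)
        assert choice.probabilities[2] > 0.95

    def test_invariant_to_duplicating_the_table(self, small_table):
        obs = small_table.stat_matrix()[10]
        doubled = A.ReferenceTable(
            data=pd.concat([small_table.data] * 2, ignore_index=True),
            mads=small_table.mads, priors=small_table.priors, config=small_table.config,
        )
        p1 = A.direct_posterior(small_table, obs, n_closest=50).probabilities
        p2 = A.direct_posterior(doubled, obs, n_closest=100).probabilities
        assert p1 == p2

    def test_n_closest_larger_than_table_raises(self, small_table):
        with pytest.raises(ValueError):
            A.direct_posterior(small_table, small_table.stat_matrix()[0], n_closest=10**6)


class TestLogisticPosterior:
    def test_separable_rows_give_near_certain_choice(self):
        table = _planted_table(shift=0.3, seed=5)  # complete separation
        obs = table.stat_matrix()[table.data["scenario"] == 2].mean(axis=0)
        choice = A.logistic_posterior(table, obs, n_closest=400, n_bootstrap=0)
        assert choice.probabilities[2] > 1 - 1e-3

    def test_label_shuffle_centers_on_half(self):
        table = _planted_table(shift=0.0, seed=6)
        obs = table.stat_matrix().mean(axis=0)
        choice = A.logistic_posterior(
            table, obs, n_closest=400, n_bootstrap=50, rng=np.random.default_rng(1)
        )
        assert choice.probabilities[2] == pytest.approx(0.5, abs=0.2)
        lo, hi = choice.intervals[2]
        assert lo <= 0.5 <= hi

    def test_agrees_with_direct_on_planted_separation(self):
        rng = np.random.default_rng(8)
        agree = 0
        for rep in range(20):
            table = _planted_table(shift=0.1, seed=100 + rep)
            scen = 1 + int(rng.random() < 0.5)
            obs = table.stat_matrix()[table.data["scenario"] == scen][
                rng.integers(0, 200)
            ]
            d = A.direct_posterior(table, obs, n_closest=100).best()
            l = A.logistic_posterior(table, obs, n_closest=400, n_bootstrap=0).best()
            agree += d == l
        assert agree >= 19

    def test_degenerate_selection_warns(self):
        table = _planted_table(shift=5.0, seed=9)
        obs = table.stat_matrix()[table.data["scenario"] == 2].mean(axis=0)
        with pytest.warns(UserWarning, match="absent"):
            choice = A.logistic_posterior(table, obs, n_closest=50, n_bootstrap=0)
        assert choice.probabilities[2] == 1.0


class TestEstimateParameters:
    def test_quantiles_ordered_and_inside_prior(self, small_table):
        obs = small_table.stat_matrix()[300]
        post = A.estimate_parameters(small_table, obs, 2, fraction=0.25)
        t = post.table
        assert (t["q025"] <= t["median"]).all() and (t["median"] <= t["q975"]).all()
        for name in t.index:
            lo, hi = small_table.priors.bounds[name]
            assert lo <= t.loc[name, "median"] <= hi

    def test_constant_statistic_is_ignored(self, small_table):
        obs = small_table.stat_matrix()[120].copy()
        t1 = A.ReferenceTable(
            data=small_table.data.copy(), mads=small_table.mads.copy(),
            priors=small_table.priors, config=small_table.config,
        )
        t1.data["adm"] = 0.3
        t1.mads["adm"] = 0.0
        obs1 = obs.copy()
        obs1[10] = 0.3
        t2 = A.ReferenceTable(
            data=t1.data.copy(), mads=t1.mads.copy(),
            priors=small_table.priors, config=small_table.config,
        )
        t2.data["adm"] = 0.9   # a different constant must not matter
        obs2 = obs.copy()
        obs2[10] = 0.9
        p1 = A.estimate_parameters(t1, obs1, 2, fraction=0.25)
        p2 = A.estimate_parameters(t2, obs2, 2, fraction=0.25)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_too_few_scenario_rows_raises(self):
        table = _planted_table(n_rows=120, seed=10)
        with pytest.raises(ValueError, match="100"):
            A.estimate_parameters(table, table.stat_matrix()[0], 2, fraction=0.5)


class TestConfusionAndValidation:
    def test_indistinguishable_generators_give_half_type1(self):
        # same generative model for both labels -> argmax is a coin flip
        table = _planted_table(n_rows=600, shift=0.0, seed=11)
        cfg = SampleConfig(n_loci=60)
        prior = PriorSpec()

        # pods simulated under real scenarios but compared against a table whose
        # labels carry no information about the statistics
        rep = A.confusion_errors(
            table, prior, cfg, n_pods=60, approach="direct",
            rng=np.random.default_rng(2), n_closest=150,
        )
        for s in (1, 2):
            assert 0.2 < rep.table.loc[s, "type1"] < 0.8

    def test_validation_reports_sane_coverage_and_prior_comparison(self, small_table):
        out = A.validate_estimation(
            small_table, small_table.priors, small_table.config, scenario=2,
            n_pods=20, rng=np.random.default_rng(3), fraction=0.2,
        )
        assert set(out.columns) >= {"rel_bias", "rel_rmse", "coverage95",
                                    "prior_rel_rmse", "prior_coverage95"}
        assert ((out["coverage95"] >= 0) & (out["coverage95"] <= 1)).all()
        assert np.isfinite(out["rel_rmse"]).all()


class TestModelCheck:
    def test_typical_observation_sits_inside_the_cloud(self, small_table):
        obs = small_table.stat_matrix()[42]
        report = A.model_check(small_table, obs)
        prior = report["prior"]
        assert 0.0 < prior["depth_percentile"] <= 1.0
        tails = np.array(list(prior["tail_probabilities"].values()))
        assert ((tails >= 0) & (tails <= 1)).all()

    def test_extreme_observation_is_flagged_outside(self, small_table):
        obs = small_table.stat_matrix().max(axis=0) + 10 * small_table.mads.to_numpy()
        report = A.model_check(small_table, obs)
        prior = report["prior"]
        assert prior["depth_percentile"] < 0.01
        assert len(prior["flagged_stats"]) > 0
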