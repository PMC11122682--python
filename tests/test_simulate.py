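"""The synthetic-data generators: dynamics, sampling structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from nfdstools import (
    GENOTYPE_CLUSTERS,
    SimulationConfig,
    gen_experiment,
    gen_genotypes,
    gen_timeseries,
)

STUDY_CLUSTER_PROBS = [0.005, 0.272, 0.088, 0.095, 0.038, 0.502]


class TestTimeseries:
    def test_same_seed_same_output(self):
        cfg = SimulationConfig(n_localities=4, years_per_locality=8, seed=3)
        s1, t1 = gen_timeseries(cfg)
        s2, t2 = gen_timeseries(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)
        s3, _ = gen_timeseries(
            SimulationConfig(n_localities=4, years_per_locality=8, seed=4)
        )
        assert not s1.equals(s3)

    def test_noise_free_recursion_is_geometric_approach(self):
        cfg = SimulationConfig(
            n_localities=1,
            years_per_locality=3,
            D_true=-0.5,
            p_eq_true=0.7,
            Ne=10**7,
            forcing_sd=0.0,
            sample_size=1000,
            seed=0,
            p0=0.9,
        )
        _, truth = gen_timeseries(cfg)
        np.testing.assert_allclose(
            truth["p_true"].to_numpy(), [0.9, 0.8, 0.75], atol=2e-3
        )

    def test_pure_drift_is_a_martingale(self):
        """With D = 0 and no forcing, E[p_T] stays at p_0."""
        cfg = SimulationConfig(
            n_localities=600,
            years_per_locality=8,
            D_true=0.0,
            p_eq_true=0.5,
            Ne=110,
            forcing_sd=0.0,
            sample_size=10,
            seed=5,
            p0=0.4,
        )
        _, truth = gen_timeseries(cfg)
        p_T = truth[truth["year"] == truth["year"].max()]["p_true"]
        # martingale: mean of final frequency ~ 0.4; se ~ sqrt(7*0.24/220)/sqrt(600)
        assert abs(p_T.mean() - 0.4) < 0.012

    def test_single_step_drift_variance_matches_wright_fisher(self):
        cfg = SimulationConfig(
            n_localities=40000,
            years_per_locality=2,
            D_true=0.0,
            p_eq_true=0.3,
            Ne=110,
            forcing_sd=0.0,
            sample_size=5,
            seed=11,
            p0=0.3,
        )
        _, truth = gen_timeseries(cfg)
        wide = truth.pivot(index="locality", columns="year", values="p_true")
        dp = wide.iloc[:, 1] - wide.iloc[:, 0]
        expected = 0.3 * 0.7 / (2 * 110)
        assert abs(dp.var() / expected - 1.0) < 0.05

    def test_nfds_pulls_toward_equilibrium(self):
        cfg = SimulationConfig(
            n_localities=2000,
            years_per_locality=2,
            D_true=-0.4,
            p_eq_true=0.6,
            Ne=10**6,
            forcing_sd=0.0,
            sample_size=5,
            seed=2,
            p0=0.8,
        )
        _, truth = gen_timeseries(cfg)
        wide = truth.pivot(index="locality", columns="year", values="p_true")
        dp = wide.iloc[:, 1] - wide.iloc[:, 0]
        assert dp.mean() < 0  # opposite sign to (p0 - p_eq) > 0

    def test_counts_conserve_sample_size(self):
        cfg = SimulationConfig(n_localities=3, years_per_locality=6, seed=9)
        series, _ = gen_timeseries(cfg)
        totals = series[["n_striped", "n_green", "n_melanic"]].sum(axis=1)
        assert (totals == cfg.sample_size).all()

    def test_host_split_partitions_the_sample(self):
        cfg = SimulationConfig(
            n_localities=3,
            years_per_locality=6,
            seed=9,
            sample_size=80,
            pct_adenostoma=np.array([20.0, 50.0, 80.0]),
        )
        series, _ = gen_timeseries(cfg)
        assert set(series["host"]) <= {"Adenostoma", "Ceanothus"}
        per_year = series.groupby(["locality", "year"])[
            ["n_striped", "n_green", "n_melanic"]
        ].sum()
        assert (per_year.sum(axis=1) == 80).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_eq_true=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(p_eq_true=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(Ne=0)
        with pytest.raises(ValueError):
            SimulationConfig(forcing_sd=-0.1)

    def test_absorbed_runs_are_flagged_not_restarted(self):
        cfg = SimulationConfig(
            n_localities=50,
            years_per_locality=25,
            D_true=0.0,
            p_eq_true=0.5,
            Ne=5,
            forcing_sd=0.0,
            sample_size=10,
            seed=1,
            p0=0.1,
        )
        _, truth = gen_timeseries(cfg)
        hit = truth.groupby("locality").apply(
            lambda g: ((g["p_true"] == 0) | (g["p_true"] == 1)).any(),
            include_groups=False,
        )
        flagged = truth.groupby("locality")["absorbed"].first()
        assert (hit == flagged).all()
        assert flagged.any()  # Ne=5 from p=0.1 fixes often


class TestExperiment:
    def test_full_grid_release_design(self):
        grid = np.arange(0, 1.0001, 0.05)
        tab = gen_experiment(grid, 20, (1.6, -0.8), seed=1)
        assert len(tab) == 21
        assert list(tab["released_striped"]) == list(range(21))
        assert (tab["released_striped"] + tab["released_green_or_melanic"] == 20).all()
        assert (tab["recaptured_striped"] <= tab["released_striped"]).all()
        assert (tab["recaptured_other"] <= tab["released_green_or_melanic"]).all()

    def test_half_frequency_splits_evenly(self):
        tab = gen_experiment([0.5], 20, (1.0, 0.0), seed=1)
        assert tab.loc[0, "released_striped"] == 10
        assert tab.loc[0, "released_green_or_melanic"] == 10

    def test_flat_fitness_recapture_tracks_release_frequency(self):
        """Equal morph recapture: pooled recapture frequency ~ release freq."""
        grid = np.repeat([0.2, 0.5, 0.8], 60)
        tab = gen_experiment(grid, 50, (1.0, 0.0), seed=4, baseline_recapture=0.5)
        for f in (0.2, 0.5, 0.8):
            sub = tab[np.isclose(tab["release_freq"], f)]
            rec_s = sub["recaptured_striped"].sum()
            rec_o = sub["recaptured_other"].sum()
            assert rec_s / (rec_s + rec_o) == pytest.approx(f, abs=0.03)

    def test_probability_clamp_warns(self):
        with pytest.warns(UserWarning):
            gen_experiment([0.5], 20, (5.0, 0.0), seed=1, baseline_recapture=0.5)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            gen_experiment([1.5], 20, (1.0, 0.0), seed=1)


class TestGenotypes:
    def test_degenerate_probability_puts_everyone_in_one_cluster(self):
        tab = gen_genotypes(50, [0, 1, 0, 0, 0, 0], seed=1)
        assert (tab["genotype_cluster"] == "striped/striped").all()

    def test_sample_cluster_counts_near_expectation(self):
        n = 602
        counts = np.zeros(6)
        for s in range(30):
            tab = gen_genotypes(n, STUDY_CLUSTER_PROBS, seed=s)
            counts += (
                tab["genotype_cluster"]
                .value_counts()
                .reindex(GENOTYPE_CLUSTERS, fill_value=0)
                .to_numpy()
            )
        mean_gs = counts[3] / 30  # green/striped heterozygotes
        assert mean_gs == pytest.approx(602 * 0.095, abs=3.0)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            gen_genotypes(10, [-0.1, 0.3, 0.2, 0.2, 0.2, 0.2], seed=1)
        with pytest.raises(ValueError):
            gen_genotypes(10, [0.5, 0.5, 0.5, 0, 0, 0], seed=1)

    def test_snp_matrix_shape_and_calls(self):
        tab, X = gen_genotypes(120, STUDY_CLUSTER_PROBS, seed=2, n_snps=150)
        assert X.shape == (120, 150)
        assert set(np.unique(X)) <= {0, 1, 2}
        assert len(tab) == 120
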