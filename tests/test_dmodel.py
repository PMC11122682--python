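"""D estimation: eligibility, equilibrium arithmetic, and model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from nfdstools import (
    DFit,
    MCMCSettings,
    SimulationConfig,
    eligible_localities,
    equilibrium_from_fit,
    equilibrium_vs_host,
    equilibrium_vs_mean,
    fit_d_model,
    fit_host_year_frequencies,
    gen_timeseries,
)
from nfdstools.dmodel import observed_mean_frequency, pool_hosts


def _series(rows):
    return pd.DataFrame(
        rows, columns=["locality", "year", "host", "n_striped", "n_green", "n_melanic"]
    )


class TestEligibility:
    def test_twelve_consecutive_years_qualify(self):
        rows = [("A", y, "pooled", 10, 10, 0) for y in range(2000, 2012)]
        assert eligible_localities(_series(rows), min_pairs=10) == ["A"]

    def test_gapped_years_have_no_pairs(self):
        rows = [("A", y, "pooled", 10, 10, 0) for y in range(2000, 2024, 2)]
        assert eligible_localities(_series(rows), min_pairs=1) == []

    def test_empty_input_gives_empty_list(self):
        assert eligible_localities(_series([])) == []

    def test_hosts_are_pooled_before_counting(self):
        rows = []
        for y in range(2000, 2012):
            host = "Adenostoma" if y % 2 == 0 else "Ceanothus"
            rows.append(("A", y, host, 10, 10, 0))
        assert eligible_localities(_series(rows), min_pairs=10) == ["A"]
        pooled = pool_hosts(_series(rows))
        assert len(pooled) == 12


class TestEquilibriumArithmetic:
    def test_closed_form(self):
        assert equilibrium_from_fit(0.35, -0.5) == (pytest.approx(0.70), True)

    def test_zero_intercept(self):
        p_eq, ok = equilibrium_from_fit(0.0, -0.3)
        assert p_eq == 0.0 and ok

    def test_out_of_range_flagged(self):
        p_eq, ok = equilibrium_from_fit(0.8, -0.5)
        assert p_eq == pytest.approx(1.6) and not ok

    def test_zero_slope_errors(self):
        with pytest.raises(ValueError):
            equilibrium_from_fit(0.3, 0.0)


class TestDModelFit:
    def test_noise_free_series_matches_ols_oracle(self, fast_mcmc):
        """Deterministic trajectories: posterior D ~ OLS slope of Δp on p."""
        cfg = SimulationConfig(
            n_localities=3,
            years_per_locality=15,
            D_true=-0.5,
            p_eq_true=np.array([0.4, 0.6, 0.75]),
            Ne=10**7,
            forcing_sd=0.0,
            sample_size=20000,
            seed=21,
            p0=np.array([0.7, 0.3, 0.45]),
        )
        series, truth = gen_timeseries(cfg)
        fit = fit_d_model(
            series, settings=fast_mcmc, seed=4, min_pairs=5, check_convergence=False
        )
        for j, loc in enumerate(fit.localities):
            p = (
                truth[truth["locality"] == loc]
                .sort_values("year")["p_true"]
                .to_numpy()
            )
            ols = linregress(p[:-1], np.diff(p)).slope
            est = fit.estimates.set_index("locality").loc[loc, "D_med"]
            assert est == pytest.approx(ols, abs=0.02)

    def test_equilibrium_is_drawwise_ratio(self, small_series, fast_mcmc):
        series, _ = small_series
        fit = fit_d_model(
            series, settings=fast_mcmc, seed=5, check_convergence=False
        )
        ratio = -fit.draws["alpha"] / fit.draws["D"]
        np.testing.assert_allclose(
            fit.estimates["p_eq_hat"].to_numpy(), np.median(ratio, axis=0)
        )

    def test_equilibrium_tracks_observed_mean(self, fast_mcmc):
        """Distinct equilibria spanning 0.2-0.9 are recovered: r >= 0.9."""
        cfg = SimulationConfig(
            n_localities=10,
            years_per_locality=20,
            D_true=-0.5,
            p_eq_true=np.linspace(0.2, 0.9, 10),
            Ne=110,
            forcing_sd=0.15,
            sample_size=200,
            seed=31,
        )
        series, _ = gen_timeseries(cfg)
        fit = fit_d_model(
            series, settings=fast_mcmc, seed=6, check_convergence=False
        )
        r, p = equilibrium_vs_mean(fit, series)
        assert r >= 0.9
        assert p < 0.01
        # all D negative under NFDS generation
        assert (fit.estimates["D_med"] < 0).all()

    def test_no_eligible_localities_errors(self):
        rows = [("A", y, "pooled", 5, 5, 0) for y in (2000, 2002)]
        with pytest.raises(ValueError):
            fit_d_model(_series(rows))


class TestEquilibriumRegressions:
    def _stub_fit(self, p_eq):
        est = pd.DataFrame(
            {"locality": [f"L{i}" for i in range(len(p_eq))], "p_eq_hat": p_eq}
        )
        return DFit(estimates=est, trajectories=pd.DataFrame(), hyper={}, draws={})

    def test_identical_vectors_give_perfect_correlation(self):
        p_eq = np.array([0.2, 0.4, 0.6, 0.8])
        rows = []
        for i, q in enumerate(p_eq):
            rows += [
                (f"L{i}", y, "pooled", int(round(100 * q)), 100 - int(round(100 * q)), 0)
                for y in (2000, 2001)
            ]
        fit = self._stub_fit(p_eq)
        r, _ = equilibrium_vs_mean(fit, _series(rows))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_correlation_needs_three_localities(self):
        fit = self._stub_fit(np.array([0.2, 0.4]))
        rows = [("L0", 2000, "pooled", 10, 10, 0), ("L1", 2000, "pooled", 5, 15, 0)]
        with pytest.raises(ValueError):
            equilibrium_vs_mean(fit, _series(rows))

    def test_exactly_linear_host_relationship(self):
        pct = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        fit = self._stub_fit(0.1 + 0.008 * pct)
        res = equilibrium_vs_host(fit, pct)
        assert res["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert res["slope"] == pytest.approx(0.008)

    def test_permuted_predictor_destroys_fit(self):
        rng = np.random.default_rng(3)
        pct = np.linspace(5, 95, 10)
        fit = self._stub_fit(0.1 + 0.008 * pct + rng.normal(0, 0.01, 10))
        observed = equilibrium_vs_host(fit, pct)["r_squared"]
        shuffled = [
            equilibrium_vs_host(fit, rng.permutation(pct))["r_squared"]
            for _ in range(200)
        ]
        assert observed > 0.9
        assert np.mean(shuffled) < 0.3

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            equilibrium_vs_host(self._stub_fit(np.array([0.2, 0.4])), [1.0])


class TestHostYearModel:
    def test_single_cell_matches_beta_binomial_oracle(self, fast_mcmc):
        rows = [("A", 2000, "Adenostoma", 70, 30, 0)]
        out = fit_host_year_frequencies(_series(rows), settings=fast_mcmc, seed=7)
        assert len(out) == 1
        # weak prior: posterior median ~ 70/100
        assert out.loc[0, "freq_med"] == pytest.approx(0.70, abs=0.03)

    def test_identical_counts_give_flat_trajectory(self, fast_mcmc):
        rows = [("A", y, "Ceanothus", 40, 60, 0) for y in range(2000, 2006)]
        out = fit_host_year_frequencies(_series(rows), settings=fast_mcmc, seed=8)
        assert out["freq_med"].max() - out["freq_med"].min() < 0.05

    def test_hosts_reported_separately_and_missing_cells_absent(self, fast_mcmc):
        rows = [
            ("A", 2000, "Adenostoma", 60, 40, 0),
            ("A", 2000, "Ceanothus", 20, 80, 0),
            ("A", 2001, "Adenostoma", 55, 45, 0),
        ]
        out = fit_host_year_frequencies(_series(rows), settings=fast_mcmc, seed=9)
        assert len(out) == 3  # no (2001, Ceanothus) cell invented
        a = out[out["host"] == "Adenostoma"]["freq_med"]
        c = out[out["host"] == "Ceanothus"]["freq_med"]
        assert a.min() > c.max()


def test_observed_mean_frequency_pools_hosts():
    rows = [
        ("A", 2000, "Adenostoma", 30, 10, 0),
        ("A", 2000, "Ceanothus", 10, 30, 5),
    ]
    means = observed_mean_frequency(_series(rows))
    assert means["A"] == pytest.approx(0.5)
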