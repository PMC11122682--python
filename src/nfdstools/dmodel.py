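"""Hierarchical Bayesian estimation of the NFDS parameter D from time series.

The observational unit is a locality-by-year morph count.  Stripe
frequency is measured among pattern-scored individuals (striped vs.
green; the melanic morph does not take part in the stripe dynamics).
Hosts are pooled within a locality for the D regression; a host-split
yearly average model is provided separately for descriptive trajectories.

Model (locality j, consecutive years t):

    y_jt ~ Binomial(n_jt, p_jt)                    observation
    Δp_jt = p_{j,t+1} − p_jt ~ N(α_j + D_j p_jt, σ_j)   NFDS regression
    D_j ~ N(μ_D, τ_D)                              partial pooling

with weakly informative priors (logit-scale N(0, 1.5) on latent
frequencies, N(0, 1) on α_j and μ_D, half-N(1) on σ_j and τ_D).  The
equilibrium stripe frequency is p̂ = −α/D, computed draw-by-draw.
Missing years break the Δp chain: pairs are only formed within maximal
runs of consecutive years, and no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import MCMCSettings, run_binomial_cells_model, run_dp_model, summarize_draws
from .theory import classify_dynamics

__all__ = [
    "DFit",
    "eligible_localities",
    "pool_hosts",
    "fit_d_model",
    "equilibrium_from_fit",
    "equilibrium_vs_mean",
    "equilibrium_vs_host",
    "fit_host_year_frequencies",
]


def pool_hosts(series: pd.DataFrame) -> pd.DataFrame:
    """Sum morph counts over hosts within each locality-year."""
    return (
        series.groupby(["locality", "year"], as_index=False)[
            ["n_striped", "n_green", "n_melanic"]
        ]
        .sum()
        .sort_values(["locality", "year"])
        .reset_index(drop=True)
    )


def _consecutive_pairs(years: np.ndarray) -> int:
    years = np.sort(np.unique(years))
    return int(np.sum(np.diff(years) == 1))


def eligible_localities(series: pd.DataFrame, min_pairs: int = 10) -> list:
    """Localities with at least ``min_pairs`` consecutive-year (p, Δp) pairs.

    Hosts are pooled within a locality before counting years.
    """
    if len(series) == 0:
        return []
    pooled = pool_hosts(series)
    out = []
    for loc, g in pooled.groupby("locality"):
        if _consecutive_pairs(g["year"].to_numpy()) >= min_pairs:
            out.append(loc)
    return out


@dataclass
class DFit:
    """Posterior summaries for the hierarchical D model."""

    estimates: pd.DataFrame  # one row per locality
    trajectories: pd.DataFrame  # latent p per locality-year + Δp
    hyper: dict  # mu_D / tau_D posterior summaries
    draws: dict = field(repr=False)  # raw stacked posterior draws
    localities: list = field(default_factory=list)


def _build_arrays(pooled: pd.DataFrame, localities):
    """Flatten locality-year cells and consecutive-year pair indices."""
    y, n, year, loc_idx = [], [], [], []
    pair_from, pair_to, pair_grp = [], [], []
    cell = 0
    for j, loc in enumerate(localities):
        g = pooled[pooled["locality"] == loc].sort_values("year")
        yrs = g["year"].to_numpy()
        ys = g["n_striped"].to_numpy()
        ns = (g["n_striped"] + g["n_green"]).to_numpy()
        keep = ns > 0
        yrs, ys, ns = yrs[keep], ys[keep], ns[keep]
        start = cell
        for i in range(len(yrs)):
            y.append(ys[i])
            n.append(ns[i])
            year.append(yrs[i])
            loc_idx.append(j)
            cell += 1
        for i in range(len(yrs) - 1):
            if yrs[i + 1] - yrs[i] == 1:
                pair_from.append(start + i)
                pair_to.append(start + i + 1)
                pair_grp.append(j)
    return (
        np.asarray(y, float),
        np.asarray(n, float),
        np.asarray(year, int),
        np.asarray(loc_idx, int),
        np.asarray(pair_from, int),
        np.asarray(pair_to, int),
        np.asarray(pair_grp, int),
    )


def fit_d_model(
    series: pd.DataFrame,
    localities=None,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    min_pairs: int = 10,
    check_convergence: bool = True,
) -> DFit:
    """Fit the hierarchical latent-frequency D model.

    ``localities`` defaults to :func:`eligible_localities`.  Raises
    :class:`nfdstools.mcmc.ConvergenceError` when split-R-hat on any D_j
    exceeds the configured threshold (default 1.05).
    """
    settings = settings or MCMCSettings()
    pooled = pool_hosts(series)
    if localities is None:
        localities = eligible_localities(series, min_pairs=min_pairs)
    if not localities:
        raise ValueError("no eligible localities")
    localities = list(localities)

    y, n, year, loc_idx, pair_from, pair_to, pair_grp = _build_arrays(
        pooled, localities
    )
    draws = run_dp_model(
        y, n, year, loc_idx, len(localities), pair_from, pair_to, pair_grp,
        settings, seed, hierarchical=True, check_convergence=check_convergence,
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        p_eq_draws = -draws["alpha"] / draws["D"]

    D_med, D_lo, D_hi = summarize_draws(draws["D"])
    a_med, a_lo, a_hi = summarize_draws(draws["alpha"])
    pe_med, pe_lo, pe_hi = summarize_draws(p_eq_draws)
    s_med, _, _ = summarize_draws(draws["sigma"])
    estimates = pd.DataFrame(
        {
            "locality": localities,
            "D_med": D_med,
            "D_lo": D_lo,
            "D_hi": D_hi,
            "alpha_med": a_med,
            "alpha_lo": a_lo,
            "alpha_hi": a_hi,
            "p_eq_hat": pe_med,
            "p_eq_lo": pe_lo,
            "p_eq_hi": pe_hi,
            "p_eq_in_range": (pe_med >= 0) & (pe_med <= 1),
            "residual_sd": s_med,
            "rhat_D": draws["rhat_D"],
            "dynamics": [classify_dynamics(d).value for d in D_med],
        }
    )

    p_med, p_lo, p_hi = summarize_draws(draws["p"])
    trajectories = pd.DataFrame(
        {
            "locality": [localities[j] for j in loc_idx],
            "year": year,
            "p_med": p_med,
            "p_lo": p_lo,
            "p_hi": p_hi,
        }
    )
    dp = np.full(len(trajectories), np.nan)
    dp[pair_from] = p_med[pair_to] - p_med[pair_from]
    trajectories["dp_next"] = dp

    mu_med, mu_lo, mu_hi = summarize_draws(draws["mu_D"])
    tau_med, tau_lo, tau_hi = summarize_draws(draws["tau_D"])
    hyper = {
        "mu_D": {"median": float(mu_med), "lo": float(mu_lo), "hi": float(mu_hi)},
        "tau_D": {"median": float(tau_med), "lo": float(tau_lo), "hi": float(tau_hi)},
    }
    return DFit(
        estimates=estimates,
        trajectories=trajectories,
        hyper=hyper,
        draws=draws,
        localities=localities,
    )


def equilibrium_from_fit(alpha: float, D: float) -> tuple[float, bool]:
    """Equilibrium stripe frequency p̂ = −α/D; flags out-of-[0,1] values.

    Returns ``(p_eq, in_range)``.  Raises for D = 0 (no internal
    equilibrium: the Δp line never crosses zero at finite frequency).
    """
    if D == 0:
        raise ValueError("D = 0: no internal equilibrium")
    p_eq = -alpha / D
    return p_eq, bool(0.0 <= p_eq <= 1.0)


def observed_mean_frequency(series: pd.DataFrame) -> pd.Series:
    """Per-locality mean stripe frequency (striped / (striped + green))."""
    pooled = pool_hosts(series)
    freq = pooled["n_striped"] / (pooled["n_striped"] + pooled["n_green"])
    return freq.groupby(pooled["locality"]).mean()


def equilibrium_vs_mean(fit: DFit, series: pd.DataFrame):
    """Pearson correlation of fitted p̂ with the observed mean frequency."""
    means = observed_mean_frequency(series)
    est = fit.estimates.set_index("locality")
    common = [loc for loc in est.index if loc in means.index]
    if len(common) < 3:
        raise ValueError("need at least 3 localities for a correlation")
    r, p = stats.pearsonr(est.loc[common, "p_eq_hat"], means.loc[common])
    return float(r), float(p)


def equilibrium_vs_host(fit: DFit, pct_adenostoma):
    """Linear regression of fitted p̂ on the percent Adenostoma per locality."""
    pct = np.asarray(pct_adenostoma, dtype=float)
    p_eq = fit.estimates["p_eq_hat"].to_numpy()
    if pct.shape != p_eq.shape:
        raise ValueError("pct_adenostoma length must match the fitted localities")
    res = stats.linregress(pct, p_eq)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }


def fit_host_year_frequencies(
    series: pd.DataFrame,
    settings: MCMCSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior yearly average stripe frequency on each host plant.

    Cells are (year, host) pooled over localities, with a hierarchical
    logit-normal prior per host.  Years with no records on a host are
    absent from the output (reported as missing).
    """
    settings = settings or MCMCSettings()
    hosts = series[series["host"].isin(["Adenostoma", "Ceanothus"])]
    if len(hosts) == 0:
        raise ValueError("series carries no host-labelled records")
    cells = (
        hosts.groupby(["year", "host"], as_index=False)[["n_striped", "n_green"]]
        .sum()
    )
    cells = cells[(cells["n_striped"] + cells["n_green"]) > 0].reset_index(drop=True)
    host_codes, host_names = pd.factorize(cells["host"])
    draws = run_binomial_cells_model(
        cells["n_striped"].to_numpy(),
        (cells["n_striped"] + cells["n_green"]).to_numpy(),
        host_codes,
        len(host_names),
        settings,
        seed,
    )
    med, lo, hi = summarize_draws(draws["p"])
    out = cells[["year", "host"]].copy()
    out["freq_med"] = med
    out["freq_lo"] = lo
    out["freq_hi"] = hi
    return out
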