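"""Test for dampening oscillations: does |Δp| decline over time?

If constant NFDS with −2 < D < 0 were the only process operating, the
year-to-year change in stripe frequency would shrink as populations
converge to (or spiral into) their equilibria.  This module regresses the
absolute per-generation frequency change |Δp| on year in a hierarchical
linear model and reports the posterior probability that the per-locality
and mean slopes are negative.

By default |Δp| is computed from posterior-median latent frequencies
(plug-in); pass draw-wise trajectories for full propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import MCMCSettings, run_hier_linear_model, summarize_draws

__all__ = ["DampeningResult", "test_dampening", "abs_dp_table"]


@dataclass
class DampeningResult:
    """Per-locality slopes of |Δp| on year and dampening probabilities."""

    slopes: pd.DataFrame  # locality, slope_med/lo/hi, pp_negative
    pp_mean_negative: float  # posterior probability the mean slope < 0
    mean_slope: dict
    draws: dict = field(repr=False)


def abs_dp_table(trajectories: pd.DataFrame, from_year: int = 2000) -> pd.DataFrame:
    """|Δp| per consecutive-year pair from a latent-frequency table.

    ``trajectories`` needs columns locality, year and a frequency column
    (``p_med`` as written by the D model, or ``p``).  The pair formed from
    years (t, t+1) is indexed by the first year t.
    """
    pcol = "p_med" if "p_med" in trajectories.columns else "p"
    rows = []
    for loc, g in trajectories.groupby("locality"):
        g = g.sort_values("year")
        yrs = g["year"].to_numpy()
        p = g[pcol].to_numpy(dtype=float)
        for i in range(len(yrs) - 1):
            if yrs[i + 1] - yrs[i] == 1 and yrs[i] >= from_year:
                rows.append((loc, int(yrs[i]), abs(p[i + 1] - p[i])))
    return pd.DataFrame(rows, columns=["locality", "year", "abs_dp"])


def test_dampening(
    trajectories: pd.DataFrame,
    from_year: int = 2000,
    settings: MCMCSettings | None = None,
    seed: int = 0,
) -> DampeningResult:
    """Hierarchical regression of |Δp| on (year − from_year).

    The hypothesis of dampening oscillations predicts a negative effect of
    year.  Returns per-locality posterior probabilities that the slope is
    below zero and the posterior probability that the hierarchical mean
    slope is below zero.
    """
    settings = settings or MCMCSettings()
    tab = abs_dp_table(trajectories, from_year=from_year)
    counts = tab.groupby("locality").size()
    keep = counts[counts >= 2].index
    tab = tab[tab["locality"].isin(keep)].reset_index(drop=True)
    if len(tab) == 0:
        raise ValueError(
            f"no locality has >= 2 |Δp| values from year {from_year} onward"
        )
    loc_codes, loc_names = pd.factorize(tab["locality"])
    x = (tab["year"] - from_year).to_numpy(dtype=float)  # centered for stability
    draws = run_hier_linear_model(
        x, tab["abs_dp"].to_numpy(), loc_codes, len(loc_names), settings, seed
    )
    b = draws["b"]
    med, lo, hi = summarize_draws(b)
    slopes = pd.DataFrame(
        {
            "locality": list(loc_names),
            "slope_med": med,
            "slope_lo": lo,
            "slope_hi": hi,
            "pp_negative": (b < 0).mean(axis=0),
        }
    )
    mu_med, mu_lo, mu_hi = summarize_draws(draws["mu_b"])
    return DampeningResult(
        slopes=slopes,
        pp_mean_negative=float((draws["mu_b"] < 0).mean()),
        mean_slope={"median": float(mu_med), "lo": float(mu_lo), "hi": float(mu_hi)},
        draws=draws,
    )
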