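"""NFDS + genetic drift null distributions for fluctuation magnitude.

Simulates stripe-frequency evolution under the fitted NFDS dynamics plus
Wright–Fisher drift only (no other forcing): each generation the expected
frequency is ``p + D (p − p̂)`` and the realised frequency is a binomial
draw of ``2 Ne`` gene copies.  Each replicate is summarised as the mean
absolute per-generation change, compared one-sidedly against the observed
mean |Δp|, and evidence is combined across localities with Fisher's
method.  A sensitivity analysis maps how small Ne must be before drift
alone matches the observed fluctuation magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NullDistribution",
    "simulate_null",
    "compare_observed",
    "fisher_combined",
    "ne_sensitivity",
]


@dataclass
class NullDistribution:
    """Null replicate mean-|Δp| values and the observed comparison."""

    locality: str
    Ne: int
    null_mean_abs_dp: np.ndarray
    observed_mean_abs_dp: float
    p_value: float
    fold_excess: float


def simulate_null(
    D: float,
    p_eq: float,
    p_0: float,
    n_generations: int,
    Ne: int,
    reps: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean |Δp| per replicate under NFDS + drift alone.

    Each replicate starts at the observed initial frequency ``p_0`` and
    iterates ``n_generations`` transitions.  Fixation is an ordinary
    outcome of the binomial draw; with Δp = D (p − p̂) and D < 0 the
    deterministic step pulls fixed trajectories back into (0, 1), so no
    special handling is applied.  The expected frequency is clamped to
    [0, 1] before sampling (a valid binomial probability).
    """
    if not 0.0 <= p_0 <= 1.0:
        raise ValueError("p_0 must be in [0, 1]")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if n_generations < 1:
        raise ValueError("need at least one generation")
    if rng is None:
        rng = np.random.default_rng(seed)
    two_ne = 2 * Ne
    p = np.full(reps, float(p_0))
    acc = np.zeros(reps)
    for _ in range(n_generations):
        expected = np.clip(p + D * (p - p_eq), 0.0, 1.0)
        p_next = rng.binomial(two_ne, expected) / two_ne
        acc += np.abs(p_next - p)
        p = p_next
    return acc / n_generations


def compare_observed(null_mean_abs_dp, observed: float):
    """One-sided Monte-Carlo p (add-one corrected) and fold-excess.

    p = (#{null >= observed} + 1) / (reps + 1); fold = observed / mean(null).
    """
    null = np.asarray(null_mean_abs_dp, dtype=float)
    if null.size < 1:
        raise ValueError("need at least one null replicate")
    null_mean = null.mean()
    if null_mean == 0:
        raise ValueError("null distribution has zero mean")
    p = (np.sum(null >= observed) + 1) / (null.size + 1)
    return float(p), float(observed / null_mean)


def fisher_combined(p_values):
    """Fisher's combined probability test: χ² = −2 Σ ln p, df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def null_test_per_locality(
    estimates: pd.DataFrame,
    observed: pd.DataFrame,
    Ne: int = 110,
    reps: int = 100,
    seed: int = 0,
) -> list[NullDistribution]:
    """Run the drift null for each locality.

    ``estimates`` needs columns locality, D_med, p_eq_hat; ``observed``
    needs locality, p_0 (initial frequency), n_generations, mean_abs_dp.
    The simulated generation count matches each locality's observed series
    so mean |Δp| values are comparable.
    """
    ss = np.random.SeedSequence(seed)
    results = []
    obs = observed.set_index("locality")
    for child, (_, row) in zip(
        ss.spawn(len(estimates)), estimates.iterrows()
    ):
        loc = row["locality"]
        o = obs.loc[loc]
        null = simulate_null(
            row["D_med"],
            row["p_eq_hat"],
            float(o["p_0"]),
            int(o["n_generations"]),
            Ne,
            reps=reps,
            rng=np.random.default_rng(child),
        )
        p, fold = compare_observed(null, float(o["mean_abs_dp"]))
        results.append(
            NullDistribution(
                locality=loc,
                Ne=Ne,
                null_mean_abs_dp=null,
                observed_mean_abs_dp=float(o["mean_abs_dp"]),
                p_value=p,
                fold_excess=fold,
            )
        )
    return results


def ne_sensitivity(
    estimates: pd.DataFrame,
    observed: pd.DataFrame,
    Ne_grid=None,
    reps: int = 100,
    seed: int = 0,
    fraction_nonsignificant: float = 1.0,
    alpha: float = 0.05,
):
    """p-value grid over Ne values and the drift-compatibility threshold.

    Repeats the per-locality null comparison for each Ne in the grid
    (default 100 down to 20 in steps of 10) and reports the largest Ne at
    which at least ``fraction_nonsignificant`` of localities are
    non-significant at level ``alpha`` — i.e. the point where drift could
    begin to explain the observed fluctuations.  Returns ``(grid_df,
    threshold_ne)``; the threshold is None if no grid value qualifies.
    """
    if Ne_grid is None:
        Ne_grid = np.arange(100, 19, -10)
    Ne_grid = np.asarray(Ne_grid, dtype=int)
    if Ne_grid.size == 0:
        raise ValueError("Ne grid must be non-empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    for child, ne in zip(ss.spawn(len(Ne_grid)), Ne_grid):
        for res in null_test_per_locality(
            estimates, observed, Ne=int(ne), reps=reps,
            seed=int(child.generate_state(1)[0] % (2**31)),
        ):
            rows.append((int(ne), res.locality, res.p_value, res.fold_excess))
    grid = pd.DataFrame(rows, columns=["Ne", "locality", "p_value", "fold_excess"])
    threshold = None
    for ne in sorted(Ne_grid, reverse=True):
        sub = grid[grid["Ne"] == ne]
        if (sub["p_value"] > alpha).mean() >= fraction_nonsignificant:
            threshold = int(ne)
            break
    return grid, threshold


def observed_summary(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-locality p_0, generation count and mean |Δp| from latent medians."""
    pcol = "p_med" if "p_med" in trajectories.columns else "p"
    rows = []
    for loc, g in trajectories.groupby("locality"):
        g = g.sort_values("year")
        yrs = g["year"].to_numpy()
        p = g[pcol].to_numpy(dtype=float)
        dps = [
            abs(p[i + 1] - p[i])
            for i in range(len(yrs) - 1)
            if yrs[i + 1] - yrs[i] == 1
        ]
        if dps:
            rows.append((loc, p[0], len(dps), float(np.mean(dps))))
    return pd.DataFrame(
        rows, columns=["locality", "p_0", "n_generations", "mean_abs_dp"]
    )
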