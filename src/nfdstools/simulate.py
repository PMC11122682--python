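"""Synthetic morph-count, transplant-experiment, and genotype data.

Generators emulating the statistical structure of replicated long-term
morph-frequency surveys in a univoltine insect with three heritable
color-pattern morphs (striped, green/unstriped, melanic):

* :func:`gen_timeseries` — per-locality stripe-frequency trajectories
  evolving by linear NFDS, optional exogenous logit-scale forcing, and
  Wright–Fisher binomial drift at ``2*Ne`` gene copies, observed through
  binomial sampling of finite yearly field samples.
* :func:`gen_experiment` — release/recapture tables for a transplant
  experiment that varies the released stripe frequency along a grid of
  bushes, with morph-specific recapture probabilities set by a linear or
  sigmoidal relative-fitness function.
* :func:`gen_genotypes` — individuals drawn from six structural-variant
  genotype clusters (unordered pairs over the green/striped/melanic
  haplotypes), optionally with a cluster-structured 0/1/2 SNP matrix that
  is separable in the top two principal components.

Every generator is a pure function of its arguments and seed: identical
inputs yield bitwise-identical tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "HAPLOTYPES",
    "GENOTYPE_CLUSTERS",
    "gen_timeseries",
    "gen_experiment",
    "gen_genotypes",
    "linear_fitness",
    "sigmoidal_fitness",
]

#: the three structural-variant haplotypes segregating at the color-pattern loci
HAPLOTYPES = ("green", "striped", "melanic")

#: the six unordered genotype clusters, homozygotes first
GENOTYPE_CLUSTERS = (
    "green/green",
    "striped/striped",
    "melanic/melanic",
    "green/striped",
    "green/melanic",
    "striped/melanic",
)

SERIES_COLUMNS = ["locality", "year", "host", "n_striped", "n_green", "n_melanic"]


@dataclass
class SimulationConfig:
    """Study conditions for a replicated morph-frequency time series.

    Defaults mirror the structure of the long-term field dataset the
    analyses are designed for: 10 localities followed for 14 consecutive
    yearly samples (one generation per year), roughly 70 individuals
    scored per locality-year, NFDS with locality-specific equilibria,
    drift at an effective size of 110, and moderate exogenous forcing.
    """

    n_localities: int = 10
    years_per_locality: int = 14
    D_true: "float | np.ndarray" = -0.48
    p_eq_true: "float | np.ndarray | None" = None  # default: spread over (0.25, 0.85)
    Ne: int = 110
    forcing_sd: float = 0.15
    sample_size: int = 70
    seed: int = 0
    start_year: int = 2000
    p0: "float | np.ndarray | None" = None
    melanic_freq: float = 0.05
    pct_adenostoma: "np.ndarray | None" = None

    def __post_init__(self):
        self.D_true = np.broadcast_to(
            np.asarray(self.D_true, dtype=float), (self.n_localities,)
        ).copy()
        if self.p_eq_true is None:
            self.p_eq_true = (
                np.linspace(0.25, 0.85, self.n_localities)
                if self.n_localities > 1
                else np.array([0.55])
            )
        self.p_eq_true = np.broadcast_to(
            np.asarray(self.p_eq_true, dtype=float), (self.n_localities,)
        ).copy()
        if np.any((self.p_eq_true <= 0) | (self.p_eq_true >= 1)):
            raise ValueError("p_eq_true must lie in the open interval (0, 1)")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.forcing_sd < 0:
            raise ValueError("forcing_sd must be non-negative")
        if self.n_localities < 1 or self.years_per_locality < 2:
            raise ValueError("need at least 1 locality and 2 years")
        if self.sample_size < 1:
            raise ValueError("sample_size must be positive")
        if self.p0 is None:
            # populations are observed away from their equilibria (external
            # forcing keeps them there); start displaced by +/-0.2,
            # alternating sign across localities
            sign = np.where(np.arange(self.n_localities) % 2 == 0, 1.0, -1.0)
            self.p0 = np.clip(self.p_eq_true + 0.2 * sign, 0.02, 0.98)
        else:
            self.p0 = np.broadcast_to(
                np.asarray(self.p0, dtype=float), (self.n_localities,)
            ).copy()
        if self.pct_adenostoma is not None:
            self.pct_adenostoma = np.asarray(self.pct_adenostoma, dtype=float)
            if self.pct_adenostoma.shape != (self.n_localities,):
                raise ValueError("pct_adenostoma must have one entry per locality")


def _locality_names(n: int) -> list[str]:
    return [f"L{i+1:02d}" for i in range(n)]


def gen_timeseries(config: SimulationConfig):
    """Simulate observed morph counts and the underlying true trajectory.

    The true stripe frequency evolves each generation by
    ``p* = p + D (p − p̂)``; exogenous forcing adds Normal(0, forcing_sd)
    noise on the logit scale; genetic drift then resamples
    ``p' = Binomial(2 Ne, ·) / (2 Ne)``.  Observed counts are a binomial
    sample of ``sample_size`` individuals: melanics at an independent,
    time-constant frequency, the remainder split striped vs. green at the
    current true stripe frequency.  If ``pct_adenostoma`` is given, each
    yearly sample is further split across the two host plants.

    Returns ``(series, truth)``: a long-format count table with columns
    locality/year/host/n_striped/n_green/n_melanic, and a truth table with
    the latent per-year stripe frequency and an ``absorbed`` flag marking
    localities whose true frequency hit 0 or 1 (returned as-is, no
    restarts).
    """
    rng = np.random.default_rng(config.seed)
    names = _locality_names(config.n_localities)
    T = config.years_per_locality
    years = config.start_year + np.arange(T)

    p = np.clip(np.asarray(config.p0, dtype=float), 0.0, 1.0)
    two_ne = 2 * config.Ne

    traj = np.empty((config.n_localities, T))
    traj[:, 0] = p
    for t in range(1, T):
        p_star = p + config.D_true * (p - config.p_eq_true)
        p_star = np.clip(p_star, 0.0, 1.0)
        if config.forcing_sd > 0:
            interior = (p_star > 0) & (p_star < 1)
            noisy = logit(np.clip(p_star, 1e-12, 1 - 1e-12))
            noisy = noisy + rng.normal(0.0, config.forcing_sd, size=p_star.shape)
            p_star = np.where(interior, expit(noisy), p_star)
        p = rng.binomial(two_ne, p_star) / two_ne
        traj[:, t] = p

    absorbed = np.any((traj == 0.0) | (traj == 1.0), axis=1)

    records = []
    for j, name in enumerate(names):
        for t in range(T):
            n = config.sample_size
            n_mel = rng.binomial(n, config.melanic_freq)
            n_pattern = n - n_mel
            n_str = rng.binomial(n_pattern, traj[j, t])
            n_grn = n_pattern - n_str
            if config.pct_adenostoma is None:
                records.append((name, int(years[t]), "pooled", n_str, n_grn, n_mel))
            else:
                w = config.pct_adenostoma[j] / 100.0
                a_str = rng.binomial(n_str, w)
                a_grn = rng.binomial(n_grn, w)
                a_mel = rng.binomial(n_mel, w)
                records.append(
                    (name, int(years[t]), "Adenostoma", a_str, a_grn, a_mel)
                )
                records.append(
                    (
                        name,
                        int(years[t]),
                        "Ceanothus",
                        n_str - a_str,
                        n_grn - a_grn,
                        n_mel - a_mel,
                    )
                )
    series = pd.DataFrame.from_records(records, columns=SERIES_COLUMNS)
    # host-split rows can have zero totals for tiny samples; drop those to
    # respect the "total per record >= 1" contract
    series = series[
        series[["n_striped", "n_green", "n_melanic"]].sum(axis=1) >= 1
    ].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "locality": np.repeat(names, T),
            "year": np.tile(years, config.n_localities),
            "p_true": traj.ravel(),
            "absorbed": np.repeat(absorbed, T),
        }
    )
    if absorbed.any():
        logger.info(
            "%d locality(ies) hit an absorbing frequency (0 or 1); flagged",
            int(absorbed.sum()),
        )
    return series, truth


def linear_fitness(p, a: float, b: float):
    """Linear relative fitness of the striped morph: ``w(p) = a + b p``."""
    return a + b * np.asarray(p, dtype=float)


def sigmoidal_fitness(p, lower: float, upper: float, midpoint: float, steepness: float):
    """Four-parameter logistic relative fitness, decreasing in p for steepness > 0."""
    p = np.asarray(p, dtype=float)
    z = np.clip(steepness * (p - midpoint), -60.0, 60.0)
    return lower + (upper - lower) / (1.0 + np.exp(z))


def gen_experiment(
    release_freq_grid,
    n_per_bush: int,
    fitness_params,
    seed: int,
    baseline_recapture: float = 0.5,
    form: str = "linear",
    n_blocks: "int | None" = None,
) -> pd.DataFrame:
    """Simulate a release/recapture transplant experiment.

    One bush per grid frequency; ``round(p * n_per_bush)`` striped insects
    (round-half-to-even, as numpy rounds) and the remainder green are
    released.  The green recapture probability is ``baseline_recapture``;
    the striped recapture probability is ``baseline * w(p)`` where ``w`` is
    the relative-fitness function (``linear_fitness`` with params ``(a, b)``
    or ``sigmoidal_fitness`` with ``(lower, upper, midpoint, steepness)``).
    Probabilities are clamped to [0.01, 0.99]; parameter choices that hit
    the clamp trigger a warning.
    """
    grid = np.asarray(release_freq_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("release frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)

    released_striped = np.rint(grid * n_per_bush).astype(int)
    released_other = n_per_bush - released_striped

    if form == "linear":
        w = linear_fitness(grid, *fitness_params)
    elif form == "sigmoidal":
        w = sigmoidal_fitness(grid, *fitness_params)
    else:
        raise ValueError(f"unknown fitness form {form!r}")

    q_g = np.full_like(grid, baseline_recapture)
    q_s = baseline_recapture * w
    if np.any((q_s < 0.01) | (q_s > 0.99)):
        warnings.warn(
            "striped recapture probabilities clamped to [0.01, 0.99]",
            stacklevel=2,
        )
    q_s = np.clip(q_s, 0.01, 0.99)
    q_g = np.clip(q_g, 0.01, 0.99)

    table = pd.DataFrame(
        {
            "bush": [f"B{i+1:02d}" for i in range(len(grid))],
            "block": (
                [f"blk{(i % n_blocks) + 1}" for i in range(len(grid))]
                if n_blocks
                else [None] * len(grid)
            ),
            "release_freq": grid,
            "released_striped": released_striped,
            "released_green_or_melanic": released_other,
            "recaptured_striped": rng.binomial(released_striped, q_s),
            "recaptured_other": rng.binomial(released_other, q_g),
        }
    )
    return table


def gen_genotypes(
    n: int,
    cluster_probs,
    seed: int,
    n_snps: "int | None" = None,
    profile_contrast: float = 0.4,
):
    """Draw individuals from the six-cluster genotype multinomial.

    ``cluster_probs`` follows the order of :data:`GENOTYPE_CLUSTERS`.
    If ``n_snps`` is given, each haplotype gets a characteristic SNP
    allele-frequency profile (``0.5 ± profile_contrast`` on
    haplotype-specific blocks) and each individual's 0/1/2 genotype is the
    sum of two Bernoulli draws from its two haplotypes' profiles, so the
    six clusters separate in the top two principal components.

    Returns a table of individuals with their true cluster labels, and
    additionally the SNP matrix when ``n_snps`` is requested.
    """
    probs = np.asarray(cluster_probs, dtype=float)
    if probs.shape != (6,):
        raise ValueError("cluster_probs must have exactly 6 entries")
    if np.any(probs < 0):
        raise ValueError("cluster probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("cluster probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    labels = rng.choice(6, size=n, p=probs / probs.sum())
    table = pd.DataFrame(
        {
            "individual": [f"ind{i+1:04d}" for i in range(n)],
            "genotype_cluster": [GENOTYPE_CLUSTERS[k] for k in labels],
        }
    )
    if n_snps is None:
        return table

    # haplotype-specific allele-frequency profiles: each haplotype elevates
    # its own third of the SNPs, keeping clusters linearly separable on PC1/2
    base = np.full((3, n_snps), 0.5 - profile_contrast / 2)
    thirds = np.array_split(np.arange(n_snps), 3)
    for h, idx in enumerate(thirds):
        base[h, idx] = 0.5 + profile_contrast

    pair_index = {
        0: (0, 0),  # green/green
        1: (1, 1),  # striped/striped
        2: (2, 2),  # melanic/melanic
        3: (0, 1),  # green/striped
        4: (0, 2),  # green/melanic
        5: (1, 2),  # striped/melanic
    }
    geno = np.empty((n, n_snps), dtype=np.int8)
    for i, k in enumerate(labels):
        h1, h2 = pair_index[int(k)]
        geno[i] = rng.binomial(1, base[h1]) + rng.binomial(1, base[h2])
    return table, geno
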