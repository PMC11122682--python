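"""Heterozygote-excess test at structural-variant color-pattern loci.

Individuals genotyped at SNPs inside the color-pattern loci fall into six
clusters in principal-component space — the unordered genotype pairs over
the three structural haplotypes (green, striped, melanic).  This module
assigns individuals to those clusters (PCA of the centered 0/1/2 genotype
matrix, then k-means on PC1/PC2), converts cluster frequencies to allele
frequencies, and tests whether green/striped heterozygotes are in excess
over the Hardy–Weinberg expectation with a binomial Monte-Carlo null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .simulate import GENOTYPE_CLUSTERS

__all__ = [
    "ClusterAssignment",
    "HetTestResult",
    "assign_clusters",
    "designate_genotypes",
    "genotype_to_allele_frequencies",
    "expected_het_frequency",
    "het_excess_test",
]


@dataclass
class ClusterAssignment:
    """PCA scores and k-means labels for each individual."""

    table: pd.DataFrame  # individual, PC1, PC2, cluster
    centroids: np.ndarray
    inertia: float


@dataclass
class HetTestResult:
    """Hardy–Weinberg quantities and the Monte-Carlo excess test."""

    genotype_freqs: dict
    allele_freqs: dict
    expected_het_freq: float
    expected_het_count: float
    observed_het_count: int
    n: int
    p_value: float
    reps: int


def assign_clusters(
    genotype_matrix: np.ndarray,
    k: int = 6,
    n_starts: int = 20,
    max_iter: int = 500,
    seed: int = 0,
    individuals=None,
) -> ClusterAssignment:
    """PCA of the genotype matrix, then k-means on (PC1, PC2).

    The matrix is column-mean-centered (covariance PCA, no scaling).  The
    best inertia over ``n_starts`` k-means initialisations is retained;
    results are deterministic under a fixed seed.
    """
    X = np.asarray(genotype_matrix, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least {k} individuals")
    scores = PCA(n_components=2, random_state=seed).fit_transform(
        X - X.mean(axis=0)
    )
    if np.unique(scores, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct points in PC space")
    km = KMeans(
        n_clusters=k, n_init=n_starts, max_iter=max_iter, random_state=seed
    ).fit(scores)
    if individuals is None:
        individuals = [f"ind{i+1:04d}" for i in range(X.shape[0])]
    table = pd.DataFrame(
        {
            "individual": individuals,
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
            "cluster": km.labels_,
        }
    )
    return ClusterAssignment(
        table=table, centroids=km.cluster_centers_, inertia=float(km.inertia_)
    )


def designate_genotypes(
    assignment: ClusterAssignment, phenotype_labels: pd.DataFrame
) -> pd.DataFrame:
    """Map numeric clusters to genotype names via external phenotype labels.

    ``phenotype_labels`` has columns individual, genotype_cluster (one of
    :data:`~nfdstools.simulate.GENOTYPE_CLUSTERS`), typically derived from
    scored color/pattern phenotypes of the clustered individuals.  Each
    k-means cluster is designated by the majority label among its members.
    Designation is pure relabelling: cluster frequencies are invariant to it.
    """
    merged = assignment.table.merge(phenotype_labels, on="individual")
    mapping = (
        merged.groupby("cluster")["genotype_cluster"]
        .agg(lambda s: s.mode().iloc[0])
        .to_dict()
    )
    out = assignment.table.copy()
    out["genotype"] = out["cluster"].map(mapping)
    return out


def genotype_to_allele_frequencies(cluster_freqs) -> dict:
    """Allele frequencies from the six genotype-cluster frequencies.

    ``cluster_freqs`` is a 6-vector in the order of
    :data:`~nfdstools.simulate.GENOTYPE_CLUSTERS` (or a dict keyed by those
    names).  Each allele's frequency is its homozygote frequency plus half
    of each heterozygote frequency involving it; the output sums to 1.
    """
    if isinstance(cluster_freqs, dict):
        f = np.array([cluster_freqs[g] for g in GENOTYPE_CLUSTERS], dtype=float)
    else:
        f = np.asarray(cluster_freqs, dtype=float)
    if f.shape != (6,):
        raise ValueError("expected 6 genotype-cluster frequencies")
    if np.any(f < 0):
        raise ValueError("genotype frequencies must be non-negative")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("genotype frequencies must sum to 1")
    gg, ss, mm, gs, gm, sm = f
    return {
        "green": gg + 0.5 * (gs + gm),
        "striped": ss + 0.5 * (gs + sm),
        "melanic": mm + 0.5 * (gm + sm),
    }


def expected_het_frequency(allele_freqs: dict, a: str = "green", b: str = "striped"):
    """Hardy–Weinberg expected frequency of the a/b heterozygote: 2 p_a p_b."""
    return 2.0 * allele_freqs[a] * allele_freqs[b]


def het_excess_test(
    observed_het: int,
    n: int,
    expected_het_freq: float,
    reps: int = 1000,
    seed: int = 0,
    correction: str = "add_one",
    genotype_freqs: dict | None = None,
    allele_freqs: dict | None = None,
) -> HetTestResult:
    """One-sided Monte-Carlo test for heterozygote excess.

    Draws ``reps`` samples from Binomial(n, expected_het_freq) and reports
    the fraction of draws at or above the observed heterozygote count.
    ``correction='add_one'`` (default) uses (k + 1)/(reps + 1), which
    cannot return 0; ``correction='plain'`` uses k/reps.  Ties count
    toward the tail (>=) in both cases.
    """
    if not 0 <= observed_het <= n:
        raise ValueError("observed_het must be between 0 and n")
    if not 0.0 < expected_het_freq < 1.0:
        raise ValueError("expected_het_freq must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    null = rng.binomial(n, expected_het_freq, size=reps)
    k = int(np.sum(null >= observed_het))
    if correction == "add_one":
        p = (k + 1) / (reps + 1)
    elif correction == "plain":
        p = k / reps
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return HetTestResult(
        genotype_freqs=genotype_freqs or {},
        allele_freqs=allele_freqs or {},
        expected_het_freq=float(expected_het_freq),
        expected_het_count=float(n * expected_het_freq),
        observed_het_count=int(observed_het),
        n=int(n),
        p_value=float(p),
        reps=int(reps),
    )


def exact_het_tail(observed_het: int, n: int, expected_het_freq: float) -> float:
    """Exact binomial upper-tail P(X >= observed); the Monte-Carlo limit."""
    return float(stats.binom.sf(observed_het - 1, n, expected_het_freq))
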