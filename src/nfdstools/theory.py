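"""Closed-form single-generation allele/morph-frequency change.

Deterministic (drift-free) expectations for the per-generation change
``Δp`` of a focal allele or morph frequency ``p`` under negative
frequency-dependent selection (NFDS), over/underdominance, directional
selection, and mainland-island migration, together with the classification
of the long-run dynamics implied by the NFDS parameter ``D``.

Under NFDS the linearised dynamics near an internal equilibrium ``p̂`` are

    Δp = D (p − p̂)

where ``D`` is the slope of Δp on p at the equilibrium (Lewontin's D).
The sign and magnitude of D determine whether trajectories converge,
oscillate with dampening, cycle stably, or diverge.
"""

from __future__ import annotations

import logging
import math
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Dynamics",
    "delta_p_nfds",
    "delta_p_overdominance",
    "delta_p_underdominance",
    "delta_p_directional",
    "delta_p_migration",
    "classify_dynamics",
    "iterate_nfds",
    "theory_curves",
]

#: tolerance for identifying the boundary values D = 0, −1, −2
BOUNDARY_TOL = 1e-9


class Dynamics(str, Enum):
    """Qualitative long-run dynamics implied by the NFDS parameter D."""

    positive_FDS = "positive_FDS"
    converging = "converging"
    dampened_oscillation = "dampened_oscillation"
    stable_oscillation = "stable_oscillation"
    diverging_oscillation = "diverging_oscillation"


def delta_p_nfds(p, D, p_eq):
    """Per-generation change under linear NFDS: ``D * (p - p_eq)``."""
    return D * (np.asarray(p, dtype=float) - p_eq)


def delta_p_overdominance(p, s1, s2):
    """Heterozygote advantage: ``p(1-p)[s2 - p(s1+s2)]``.

    ``s1`` and ``s2`` are the selective deviations of the two homozygotes
    relative to the heterozygote; positive values give an internal stable
    equilibrium at ``s2/(s1+s2)``.
    """
    p = np.asarray(p, dtype=float)
    return p * (1.0 - p) * (s2 - p * (s1 + s2))


def delta_p_underdominance(p, s1, s2):
    """Heterozygote disadvantage; same form with negative ``s2``."""
    return delta_p_overdominance(p, s1, s2)


def delta_p_directional(p, s, h):
    """Directional selection: ``s p(1-p)[p + h(1-2p)]``.

    ``s`` is the homozygote selection coefficient and ``h`` in [0, 1] the
    heterozygote effect (h=0.5 is additive/codominant).
    """
    p = np.asarray(p, dtype=float)
    return s * p * (1.0 - p) * (p + h * (1.0 - 2.0 * p))


def delta_p_migration(p, m, p_m):
    """Mainland-island gene flow: ``[p(1-m) + p_m m] - p = m (p_m - p)``."""
    p = np.asarray(p, dtype=float)
    return (p * (1.0 - m) + p_m * m) - p


def classify_dynamics(D: float, tol: float = BOUNDARY_TOL) -> Dynamics:
    """Classify the expected dynamics of ``p`` under NFDS from ``D``.

    −1 < D < 0 gives gradual convergence to the equilibrium, −2 < D < −1
    dampened oscillations, D = −2 stable (constant-amplitude) oscillations,
    D < −2 diverging oscillations, and D > 0 positive frequency dependence.
    The boundary values D = 0 and D = −1 lie between open intervals; they
    are assigned to the adjacent class toward zero (0 → positive_FDS edge is
    treated as converging-with-zero-force, i.e. ``converging``; −1 →
    ``converging``) so classification is total and deterministic.
    """
    if not math.isfinite(D):
        raise ValueError(f"D must be finite, got {D!r}")
    if abs(D + 2.0) <= tol:
        return Dynamics.stable_oscillation
    if D < -2.0:
        return Dynamics.diverging_oscillation
    if D < -1.0 - tol:
        return Dynamics.dampened_oscillation
    if D <= tol:
        # covers −1−tol ≤ D ≤ tol; boundaries 0 and −1 fold into this class
        if abs(D) <= tol or abs(D + 1.0) <= tol:
            logger.info(
                "D=%g is a boundary value; assigned to 'converging' "
                "(adjacent class toward zero)", D,
            )
        return Dynamics.converging
    return Dynamics.positive_FDS


def iterate_nfds(p0: float, D: float, p_eq: float, n_steps: int) -> np.ndarray:
    """Iterate the deterministic NFDS map ``p ← p + D (p − p̂)``.

    Frequencies are clamped to [0, 1] after each step; for the parameter
    ranges of interest (|D| ≤ 2) the clamp is inactive for interior starts.
    Returns the trajectory including ``p0`` (length ``n_steps + 1``).
    """
    traj = np.empty(n_steps + 1)
    traj[0] = p = float(p0)
    for i in range(n_steps):
        p = min(1.0, max(0.0, p + D * (p - p_eq)))
        traj[i + 1] = p
    return traj


def theory_curves(p_grid=None, **params) -> "dict[str, np.ndarray]":
    """Evaluate every Δp(p) curve on a grid; used by the CLI export.

    Parameters default to illustrative values: D=−0.5, p_eq=0.7,
    s1=s2=0.3 (overdominance), s1=s2=−0.3 (underdominance), s=0.1, h=0.5,
    m=0.1, p_m=0.8.
    """
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, 101)
    p_grid = np.asarray(p_grid, dtype=float)
    D = params.get("D", -0.5)
    p_eq = params.get("p_eq", 0.7)
    return {
        "p": p_grid,
        "nfds": delta_p_nfds(p_grid, D, p_eq),
        "overdominance": delta_p_overdominance(
            p_grid, params.get("s1", 0.3), params.get("s2", 0.3)
        ),
        "underdominance": delta_p_underdominance(
            p_grid, params.get("s1_under", -0.3), params.get("s2_under", -0.3)
        ),
        "directional": delta_p_directional(
            p_grid, params.get("s", 0.1), params.get("h", 0.5)
        ),
        "migration": delta_p_migration(
            p_grid, params.get("m", 0.1), params.get("p_m", 0.8)
        ),
    }
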