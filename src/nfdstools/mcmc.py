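"""Gibbs-within-Metropolis samplers for the hierarchical Bayesian models.

Three model families share this machinery:

* the time-series NFDS model — latent logit-scale stripe frequencies with
  binomial observation likelihoods, a per-locality Gaussian regression of
  Δp on p (intercept α_j, slope D_j), and a hierarchical prior pooling the
  D_j across localities;
* hierarchical Gaussian linear regressions with observed responses (the
  |Δp|-on-year dampening model);
* hierarchical binomial cell means (the host-by-year frequency model).

Conjugate conditionals (Gaussian regression coefficients, hyper-means) are
sampled in closed form; latent frequencies and scale parameters use
adaptive random-walk Metropolis steps.  Latent frequencies are updated in
a checkerboard (even/odd year) schedule: a pair (t, t+1) always couples
cells of opposite parity, so joint per-cell acceptance within a parity
class is exact.

Priors (weakly informative, scale-appropriate): latent logit frequencies
N(0, 1.5); intercepts and hyper-means N(0, 1); slopes hierarchically
N(mu, tau); residual SDs and hyper-SDs half-Normal(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["MCMCSettings", "ConvergenceError", "summarize_draws"]

_LATENT_PRIOR_SD = 1.5
_COEF_PRIOR_SD = 1.0
_SCALE_PRIOR_SD = 1.0


@dataclass
class MCMCSettings:
    """Chain configuration; defaults suit full analyses, tests pass smaller."""

    chains: int = 4
    warmup: int = 2000
    samples: int = 2000
    rhat_threshold: float = 1.05

    def scaled(self, factor: float) -> "MCMCSettings":
        return MCMCSettings(
            chains=self.chains,
            warmup=max(100, int(self.warmup * factor)),
            samples=max(100, int(self.samples * factor)),
            rhat_threshold=self.rhat_threshold,
        )


class ConvergenceError(RuntimeError):
    """Raised when split-R-hat exceeds the configured threshold."""


def _half_normal_logpdf(x, scale):
    return -0.5 * (x / scale) ** 2


def _adapt(step, accept_rate, target=0.44, rate=0.6):
    return step * np.exp(rate * (accept_rate - target))


def summarize_draws(draws: np.ndarray, axis: int = 0):
    """Posterior median and 95% equal-tailed probability interval."""
    med = np.median(draws, axis=axis)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=axis)
    return med, lo, hi


def split_rhat(chains_draws: np.ndarray) -> np.ndarray:
    """Split-R-hat over an array shaped (chain, draw, ...).

    Thin wrapper kept local so the samplers need no arviz import at
    sampling time; cross-checked against ``arviz.rhat`` in the test suite.
    """
    c, n = chains_draws.shape[:2]
    half = n // 2
    split = np.concatenate(
        [chains_draws[:, :half], chains_draws[:, half : 2 * half]], axis=0
    )
    m, n2 = split.shape[:2]
    means = split.mean(axis=1)
    vars_ = split.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = n2 * means.var(axis=0, ddof=1)
    var_hat = (n2 - 1) / n2 * W + B / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


def _sample_bivariate_regression(
    n_pairs, S_x, S_xx, S_y, S_xy, sigma, prior_mean_b, prior_sd_a, prior_sd_b, rng
):
    """Conjugate draw of (intercept a, slope b) per group, vectorized.

    Model: y_i ~ N(a + b x_i, sigma) within each group, with independent
    Gaussian priors a ~ N(0, prior_sd_a), b ~ N(prior_mean_b, prior_sd_b).
    Returns arrays (a, b).
    """
    s2 = sigma**2
    A11 = n_pairs / s2 + 1.0 / prior_sd_a**2
    A12 = S_x / s2
    A22 = S_xx / s2 + 1.0 / prior_sd_b**2
    b1 = S_y / s2
    b2 = S_xy / s2 + prior_mean_b / prior_sd_b**2
    det = A11 * A22 - A12**2
    # posterior mean
    m1 = (A22 * b1 - A12 * b2) / det
    m2 = (A11 * b2 - A12 * b1) / det
    # sample via Cholesky of the 2x2 covariance (inverse precision)
    c11 = A22 / det
    c12 = -A12 / det
    c22 = A11 / det
    L11 = np.sqrt(c11)
    L21 = c12 / L11
    L22 = np.sqrt(np.maximum(c22 - L21**2, 1e-300))
    z1 = rng.standard_normal(np.shape(m1))
    z2 = rng.standard_normal(np.shape(m1))
    a = m1 + L11 * z1
    b = m2 + L21 * z1 + L22 * z2
    return a, b


def _update_scales_mh(sigma, n_obs, rss, step, rng, prior_sd=_SCALE_PRIOR_SD):
    """Update per-group residual SDs by near-conjugate independence MH.

    The proposal for sigma^2 is the Inverse-Gamma matching the Gaussian
    likelihood exactly (shape (n-1)/2, scale RSS/2, which absorbs the
    sigma^2-scale Jacobian of the half-Normal prior on sigma); the
    acceptance ratio then reduces to the half-Normal prior factor and is
    ~1 for scales well below the prior SD.  This avoids the sticky
    random-walk behaviour of log-scale MH when residuals are tiny.
    Groups with fewer than 2 observations or zero RSS fall back to a
    log-scale random walk.
    """
    sigma = np.asarray(sigma, dtype=float)
    a = (np.asarray(n_obs, dtype=float) - 1.0) / 2.0
    ok = (a > 0) & (rss > 0)
    shape = np.where(ok, a, 1.0)
    x_new = (rss / 2.0) / rng.gamma(shape)
    log_acc = -(x_new - sigma**2) / (2.0 * prior_sd**2)
    accept = (np.log(rng.random(sigma.shape)) < log_acc) & ok
    out = np.where(accept, np.sqrt(np.where(ok, x_new, 1.0)), sigma)
    # random-walk fallback for degenerate groups
    if np.any(~ok):
        prop = sigma * np.exp(step * rng.standard_normal(sigma.shape))

        def logpost(s):
            with np.errstate(divide="ignore", invalid="ignore"):
                return (
                    -n_obs * np.log(s)
                    - rss / (2 * s**2)
                    + _half_normal_logpdf(s, prior_sd)
                    + np.log(s)
                )

        delta = logpost(prop) - logpost(sigma)
        acc_rw = (np.log(rng.random(sigma.shape)) < delta) & (~ok)
        out = np.where(acc_rw, prop, out)
        accept = accept | acc_rw
    return out, accept


def _update_hyper_scale_conjugate(tau, values, mu, rng, prior_sd=_SCALE_PRIOR_SD):
    """Near-conjugate independence MH for a hyper-SD (same scheme as above)."""
    k = values.size
    ss = np.sum((values - mu) ** 2)
    a = (k - 1.0) / 2.0
    if a <= 0 or ss <= 0:
        return tau, False
    x_new = (ss / 2.0) / rng.gamma(a)
    log_acc = -(x_new - tau**2) / (2.0 * prior_sd**2)
    if np.log(rng.random()) < log_acc:
        return float(np.sqrt(x_new)), True
    return tau, False


def _update_hyper_mean(values, tau, prior_sd, rng):
    """Conjugate draw of a hyper-mean with N(0, prior_sd) prior."""
    k = values.size
    prec = k / tau**2 + 1.0 / prior_sd**2
    mean = (values.sum() / tau**2) / prec
    return mean + rng.standard_normal() / np.sqrt(prec)


def _update_hyper_scale(tau, values, mu, step, rng, prior_sd=_SCALE_PRIOR_SD):
    """MH update of a hyper-SD on the log scale."""
    k = values.size
    ss = np.sum((values - mu) ** 2)
    prop = tau * np.exp(step * rng.standard_normal())

    def logpost(t):
        return (
            -k * np.log(t)
            - ss / (2 * t**2)
            + _half_normal_logpdf(t, prior_sd)
            + np.log(t)
        )

    if np.log(rng.random()) < logpost(prop) - logpost(tau):
        return prop, True
    return tau, False


# ---------------------------------------------------------------------------
# time-series NFDS model
# ---------------------------------------------------------------------------


def _binom_logit_loglik(ell, y, n):
    return y * ell - n * np.logaddexp(0.0, ell)


def run_dp_chain(
    y,
    n,
    year,
    loc_idx,
    n_groups,
    pair_from,
    pair_to,
    pair_grp,
    warmup,
    samples,
    rng,
    hierarchical=True,
    fixed_pred=None,
    latent_prior_sd=_LATENT_PRIOR_SD,
):
    """One chain of the latent-frequency Δp regression model.

    ``fixed_pred`` switches to the experiment variant: the regression
    predictor for pair m is the known release frequency ``fixed_pred[m]``
    instead of the latent frequency at ``pair_from`` (which is then unused
    as a predictor but still a latent response endpoint is ``pair_to``).
    With ``hierarchical=False`` (or a single group) the slope prior is
    N(0, 1) directly and no hyper-parameters are sampled.

    Returns a dict of posterior draw arrays.
    """
    N = y.size
    M = pair_from.size
    J = n_groups

    # initial latent logits at the empirical frequencies
    p_emp = (y + 0.5) / (n + 1.0)
    ell = np.log(p_emp / (1 - p_emp))
    alpha = np.zeros(J)
    Dj = np.zeros(J)
    sigma = np.full(J, 0.1)
    mu_D = 0.0
    tau_D = 0.5

    hierarchical = hierarchical and J > 1

    step_ell = np.full(N, 0.5)
    step_sig = np.full(J, 0.4)
    step_tau = 0.4
    step_shift = np.array([0.05, 0.05])
    acc_ell = np.zeros(N)
    acc_sig = np.zeros(J)
    acc_tau = 0.0
    acc_shift = 0.0
    adapt_every = 50

    parity = year % 2
    if fixed_pred is not None:
        # experiment variant: each pair touches only its latent endpoint
        upd_cell = {0: pair_to, 1: pair_to}
    else:
        # each pair couples years t and t+1 -> endpoints have opposite parity
        upd_cell = {
            par: np.where(parity[pair_from] == par, pair_from, pair_to)
            for par in (0, 1)
        }

    n_pairs_g = np.bincount(pair_grp, minlength=J).astype(float)

    out = {
        "alpha": np.empty((samples, J)),
        "D": np.empty((samples, J)),
        "sigma": np.empty((samples, J)),
        "mu_D": np.empty(samples),
        "tau_D": np.empty(samples),
        "p": np.empty((samples, N)),
    }

    def pair_ll(p_all):
        pf = fixed_pred if fixed_pred is not None else p_all[pair_from]
        pt = p_all[pair_to]
        x = pf
        mu = alpha[pair_grp] + Dj[pair_grp] * x
        return -0.5 * ((pt - pf - mu) / sigma[pair_grp]) ** 2

    total = warmup + samples
    for it in range(total):
        p = expit(ell)
        # --- latent logits, checkerboard over year parity (3 sweeps per
        # scan: latent-field moves are the mixing bottleneck)
        for par in (0, 1, 0, 1, 0, 1):
            mask = parity == par
            prop_ell = ell.copy()
            prop_ell[mask] += step_ell[mask] * rng.standard_normal(mask.sum())
            prop_p = expit(prop_ell)
            delta = np.zeros(N)
            delta[mask] = (
                _binom_logit_loglik(prop_ell[mask], y[mask], n[mask])
                - _binom_logit_loglik(ell[mask], y[mask], n[mask])
                - (prop_ell[mask] ** 2 - ell[mask] ** 2)
                / (2 * latent_prior_sd**2)
            )
            if M:
                d_pair = pair_ll(prop_p) - pair_ll(p)
                np.add.at(delta, upd_cell[par], d_pair)
            accept = np.log(rng.random(N)) < delta
            accept &= mask
            ell = np.where(accept, prop_ell, ell)
            p = expit(ell)
            acc_ell += accept

        # --- regression coefficients (conjugate)
        if M:
            pf = fixed_pred if fixed_pred is not None else p[pair_from]
            pt = p[pair_to]
            x = pf
            dp = pt - pf
            S_x = np.bincount(pair_grp, weights=x, minlength=J)
            S_xx = np.bincount(pair_grp, weights=x * x, minlength=J)
            S_y = np.bincount(pair_grp, weights=dp, minlength=J)
            S_xy = np.bincount(pair_grp, weights=x * dp, minlength=J)
            prior_mean_b = mu_D if hierarchical else 0.0
            prior_sd_b = tau_D if hierarchical else _COEF_PRIOR_SD
            alpha, Dj = _sample_bivariate_regression(
                n_pairs_g, S_x, S_xx, S_y, S_xy, sigma,
                prior_mean_b, _COEF_PRIOR_SD, prior_sd_b, rng,
            )
            # --- residual scales
            resid = dp - alpha[pair_grp] - Dj[pair_grp] * x
            rss = np.bincount(pair_grp, weights=resid**2, minlength=J)
            sigma, acc = _update_scales_mh(sigma, n_pairs_g, rss, step_sig, rng)
            acc_sig += acc

        # --- hyper-parameters
        if hierarchical:
            mu_D = _update_hyper_mean(Dj, tau_D, _COEF_PRIOR_SD, rng)
            tau_D, acc_t = _update_hyper_scale_conjugate(tau_D, Dj, mu_D, rng)
            acc_tau += acc_t

        # --- line-shift move (experiment variant): translate (alpha, D)
        # together with all response latents so regression residuals are
        # preserved exactly; breaks the slow random walk that appears when
        # sigma is small and the latents are pinned to the fitted line.
        # The shear is volume-preserving in p-space; only the logit
        # transform contributes a Jacobian.
        if fixed_pred is not None and M:
            for _ in range(2):
                d_a = step_shift[0] * rng.standard_normal()
                d_D = step_shift[1] * rng.standard_normal()
                p_new = p.copy()
                p_new[pair_to] = p[pair_to] + d_a + d_D * fixed_pred
                if np.all((p_new[pair_to] > 1e-9) & (p_new[pair_to] < 1 - 1e-9)):
                    ell_new = np.log(p_new / (1 - p_new))
                    prior_mean_b = mu_D if hierarchical else 0.0
                    prior_sd_b = tau_D if hierarchical else _COEF_PRIOR_SD
                    a_new = alpha[0] + d_a
                    D_new = Dj[0] + d_D
                    log_acc = (
                        np.sum(
                            _binom_logit_loglik(ell_new[pair_to], y[pair_to], n[pair_to])
                            - _binom_logit_loglik(ell[pair_to], y[pair_to], n[pair_to])
                        )
                        - np.sum(ell_new[pair_to] ** 2 - ell[pair_to] ** 2)
                        / (2 * latent_prior_sd**2)
                        + np.sum(
                            np.log(p[pair_to] * (1 - p[pair_to]))
                            - np.log(p_new[pair_to] * (1 - p_new[pair_to]))
                        )
                        - (a_new**2 - alpha[0] ** 2) / (2 * _COEF_PRIOR_SD**2)
                        - ((D_new - prior_mean_b) ** 2 - (Dj[0] - prior_mean_b) ** 2)
                        / (2 * prior_sd_b**2)
                    )
                    if np.log(rng.random()) < log_acc:
                        p = p_new
                        ell = ell_new
                        alpha = alpha + d_a
                        Dj = Dj + d_D
                        acc_shift += 1.0

        # --- adaptation during warmup
        if it < warmup and (it + 1) % adapt_every == 0:
            # each cell's parity appears 3x per scan
            step_ell = _adapt(step_ell, acc_ell / (3 * adapt_every))
            step_sig = _adapt(step_sig, acc_sig / adapt_every)
            step_tau = _adapt(step_tau, acc_tau / adapt_every)
            step_shift = _adapt(
                step_shift, acc_shift / (2 * adapt_every), target=0.3
            )
            acc_ell[:] = 0
            acc_sig[:] = 0
            acc_tau = 0.0
            acc_shift = 0.0

        if it >= warmup:
            k = it - warmup
            out["alpha"][k] = alpha
            out["D"][k] = Dj
            out["sigma"][k] = sigma
            out["mu_D"][k] = mu_D
            out["tau_D"][k] = tau_D
            out["p"][k] = p
    return out


def run_dp_model(
    y, n, year, loc_idx, n_groups, pair_from, pair_to, pair_grp,
    settings: MCMCSettings, seed: int,
    hierarchical=True, fixed_pred=None, check_convergence=True,
    latent_prior_sd=_LATENT_PRIOR_SD,
):
    """Run multiple chains, check split-R-hat on the slopes, stack draws."""
    ss = np.random.SeedSequence(seed)
    chains = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        chains.append(
            run_dp_chain(
                y, n, year, loc_idx, n_groups, pair_from, pair_to, pair_grp,
                settings.warmup, settings.samples, rng,
                hierarchical=hierarchical, fixed_pred=fixed_pred,
                latent_prior_sd=latent_prior_sd,
            )
        )
    stacked = {
        k: np.concatenate([c[k] for c in chains], axis=0) for k in chains[0]
    }
    rhat = split_rhat(np.stack([c["D"] for c in chains]))
    stacked["rhat_D"] = np.atleast_1d(rhat)
    if check_convergence and np.any(stacked["rhat_D"] > settings.rhat_threshold):
        bad = np.flatnonzero(stacked["rhat_D"] > settings.rhat_threshold)
        raise ConvergenceError(
            f"split-R-hat > {settings.rhat_threshold} for D in groups {bad}: "
            f"{stacked['rhat_D'][bad]}"
        )
    return stacked


# ---------------------------------------------------------------------------
# hierarchical Gaussian regression with observed responses
# ---------------------------------------------------------------------------


def run_hier_linear_model(x, yv, grp, n_groups, settings: MCMCSettings, seed: int):
    """Hierarchical y ~ a_j + b_j x with both coefficients pooled.

    Used by the dampening test (y = |Δp|, x = centered year).  Returns
    stacked draws of a, b, sigma, mu_a, mu_b, tau_a, tau_b.
    """
    x = np.asarray(x, float)
    yv = np.asarray(yv, float)
    grp = np.asarray(grp)
    J = n_groups
    n_g = np.bincount(grp, minlength=J).astype(float)
    S_x = np.bincount(grp, weights=x, minlength=J)
    S_xx = np.bincount(grp, weights=x * x, minlength=J)
    S_y = np.bincount(grp, weights=yv, minlength=J)
    S_xy = np.bincount(grp, weights=x * yv, minlength=J)

    ss = np.random.SeedSequence(seed)
    all_out = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        a = np.zeros(J)
        b = np.zeros(J)
        sigma = np.full(J, max(yv.std(), 0.05))
        mu_a, tau_a = 0.0, 0.5
        mu_b, tau_b = 0.0, 0.5
        step_sig = np.full(J, 0.4)
        step_tau = np.array([0.4, 0.4])
        acc_sig = np.zeros(J)
        acc_tau = np.zeros(2)
        out = {
            k: np.empty((settings.samples, J))
            for k in ("a", "b", "sigma")
        }
        for k in ("mu_a", "mu_b", "tau_a", "tau_b"):
            out[k] = np.empty(settings.samples)
        total = settings.warmup + settings.samples
        for it in range(total):
            # intercepts drawn conditional on slopes and vice versa would be
            # exact too, but the joint bivariate conjugate step is simpler:
            # prior a_j ~ N(mu_a, tau_a) handled by shifting the response
            a_shift, b_draw = _sample_bivariate_regression(
                n_g, S_x, S_xx, S_y - mu_a * n_g, S_xy - mu_a * S_x,
                sigma, mu_b, tau_a, tau_b, rng,
            )
            a = a_shift + mu_a
            b = b_draw
            resid_ss = (
                np.bincount(
                    grp,
                    weights=(yv - a[grp] - b[grp] * x) ** 2,
                    minlength=J,
                )
            )
            sigma, acc = _update_scales_mh(sigma, n_g, resid_ss, step_sig, rng)
            acc_sig += acc
            mu_a = _update_hyper_mean(a, tau_a, _COEF_PRIOR_SD, rng)
            mu_b = _update_hyper_mean(b, tau_b, _COEF_PRIOR_SD, rng)
            tau_a, t1 = _update_hyper_scale_conjugate(tau_a, a, mu_a, rng)
            tau_b, t2 = _update_hyper_scale_conjugate(tau_b, b, mu_b, rng)
            acc_tau += (t1, t2)
            if it < settings.warmup and (it + 1) % 50 == 0:
                step_sig = _adapt(step_sig, acc_sig / 50)
                step_tau = _adapt(step_tau, acc_tau / 50)
                acc_sig[:] = 0
                acc_tau[:] = 0
            if it >= settings.warmup:
                k = it - settings.warmup
                out["a"][k] = a
                out["b"][k] = b
                out["sigma"][k] = sigma
                out["mu_a"][k] = mu_a
                out["mu_b"][k] = mu_b
                out["tau_a"][k] = tau_a
                out["tau_b"][k] = tau_b
        all_out.append(out)
    stacked = {
        k: np.concatenate([c[k] for c in all_out], axis=0) for k in all_out[0]
    }
    stacked["rhat_b"] = np.atleast_1d(
        split_rhat(np.stack([c["b"] for c in all_out]))
    )
    return stacked


# ---------------------------------------------------------------------------
# hierarchical binomial cell means (host-by-year frequencies)
# ---------------------------------------------------------------------------


def run_binomial_cells_model(y, n, grp, n_groups, settings: MCMCSettings, seed: int):
    """Cells y_c ~ Binomial(n_c, expit(ell_c)), ell_c ~ N(mu_g, tau_g).

    ``grp`` maps each cell to its pooling group (e.g. host plant).
    Returns stacked draws of the cell frequencies ``p`` plus hyper-draws.
    """
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    grp = np.asarray(grp)
    C = y.size
    G = n_groups
    ss = np.random.SeedSequence(seed)
    all_out = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        p_emp = (y + 0.5) / (n + 1.0)
        ell = np.log(p_emp / (1 - p_emp))
        mu = np.zeros(G)
        tau = np.full(G, 1.0)
        step = np.full(C, 0.5)
        acc = np.zeros(C)
        step_tau = np.full(G, 0.4)
        acc_tau = np.zeros(G)
        out = {"p": np.empty((settings.samples, C)),
               "mu": np.empty((settings.samples, G)),
               "tau": np.empty((settings.samples, G))}
        total = settings.warmup + settings.samples
        for it in range(total):
            prop = ell + step * rng.standard_normal(C)
            delta = (
                _binom_logit_loglik(prop, y, n)
                - _binom_logit_loglik(ell, y, n)
                - ((prop - mu[grp]) ** 2 - (ell - mu[grp]) ** 2)
                / (2 * tau[grp] ** 2)
            )
            a = np.log(rng.random(C)) < delta
            ell = np.where(a, prop, ell)
            acc += a
            for g in range(G):
                sel = grp == g
                vals = ell[sel]
                mu[g] = _update_hyper_mean(vals, tau[g], _LATENT_PRIOR_SD, rng)
                tau[g], t_acc = _update_hyper_scale_conjugate(
                    tau[g], vals, mu[g], rng
                )
                acc_tau[g] += t_acc
            if it < settings.warmup and (it + 1) % 50 == 0:
                step = _adapt(step, acc / 50)
                step_tau = _adapt(step_tau, acc_tau / 50)
                acc[:] = 0
                acc_tau[:] = 0
            if it >= settings.warmup:
                k = it - settings.warmup
                out["p"][k] = expit(ell)
                out["mu"][k] = mu
                out["tau"][k] = tau
        all_out.append(out)
    return {
        k: np.concatenate([c[k] for c in all_out], axis=0) for k in all_out[0]
    }
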