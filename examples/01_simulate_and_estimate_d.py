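"""Simulate replicated morph-frequency series and estimate the NFDS parameter D.

Generates 10 localities of yearly stripe-frequency counts evolving under
negative frequency-dependent selection (D = -0.5) with drift and mild
exogenous forcing, then fits the hierarchical latent-frequency model.
"""

import numpy as np

import nfdstools as nt

cfg = nt.SimulationConfig(
    n_localities=10,
    years_per_locality=20,
    D_true=-0.5,
    p_eq_true=np.linspace(0.3, 0.8, 10),
    Ne=110,
    forcing_sd=0.15,
    sample_size=200,
    seed=1,
)
series, truth = nt.gen_timeseries(cfg)
fit = nt.fit_d_model(
    series, settings=nt.MCMCSettings(chains=2, warmup=1000, samples=1500), seed=2
)

print(fit.estimates[["locality", "D_med", "D_lo", "D_hi", "p_eq_hat", "dynamics"]]
      .round(3).to_string(index=False))
mu = fit.hyper["mu_D"]
print(f"\nhierarchical mean D: {mu['median']:.3f} [{mu['lo']:.3f}, {mu['hi']:.3f}]")
r, p = nt.equilibrium_vs_mean(fit, series)
print(f"fitted equilibrium vs observed mean frequency: Pearson r = {r:.3f}")
print(
    "\nEvery locality has a negative D (rare-morph advantage); -alpha/D is the\n"
    "frequency toward which each locality is pulled, and it tracks the\n"
    "observed long-run mean frequency."
)
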