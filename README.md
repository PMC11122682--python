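# nfdstools

Analysis of balanced color-pattern polymorphisms under **negative
frequency-dependent selection (NFDS)** — built for replicated long-term
morph-frequency surveys of the kind collected for *Timema cristinae*
stick insects, where a striped and an unstriped (green) morph fluctuate
around locality-specific equilibria year after year.

It is a library for population geneticists and field ecologists who have
(or simulate) yearly morph counts, transplant release/recapture
experiments, or structural-variant genotype data, and who want to ask:

* Is there a rare-morph advantage, and how strong is it?
* Are fluctuations converging to an equilibrium or perpetually sustained?
* Can genetic drift alone explain the observed fluctuation magnitude?
* What shape is the NFDS fitness function, and where is its equilibrium?
* Is there an excess of heterozygotes at the underlying loci?

## The model at its core

With morph frequency `p` and internal equilibrium `p̂`, the linearised
per-generation change under NFDS is

```
Δp = D (p − p̂),          D < 0 under NFDS,   p̂ = −α/D
```

where `D` (Lewontin's NFDS parameter) is the slope of Δp on p near the
equilibrium and `α` the intercept of the linear Δp model.  `D` classifies
the expected dynamics: convergence (−1 < D < 0), dampened oscillations
(−2 < D < −1), stable oscillations (D = −2), diverging oscillations
(D < −2).  `nfdstools` estimates `D`, `α`, and `p̂` per locality with a
hierarchical Bayesian state-space model — binomial morph counts over
latent frequencies, partial pooling of `D` across localities — and
surrounds that estimate with the dampening test (|Δp| on year), NFDS +
Wright–Fisher drift null simulations with Fisher-combined evidence,
Bayesian transplant-experiment models (linear vs. sigmoidal relative
fitness, morph-advantage GLM), and a Hardy–Weinberg heterozygote-excess
Monte-Carlo test.  A synthetic-data module generates morph-count series,
experiment tables, and clustered genotype matrices with the statistical
structure these analyses assume, so the whole pipeline is testable
without any field data.

## Worked example

```python
import numpy as np
import nfdstools as nt

cfg = nt.SimulationConfig(
    n_localities=10, years_per_locality=20, D_true=-0.5,
    p_eq_true=np.linspace(0.3, 0.8, 10), Ne=110,
    forcing_sd=0.15, sample_size=200, seed=1,
)
series, truth = nt.gen_timeseries(cfg)
fit = nt.fit_d_model(
    series, settings=nt.MCMCSettings(chains=2, warmup=1000, samples=1500), seed=2
)
print(fit.estimates[["locality", "D_med", "D_lo", "D_hi", "p_eq_hat", "dynamics"]])
```

prints (see `examples/01_simulate_and_estimate_d.py`):

```
locality  D_med   D_lo   D_hi  p_eq_hat   dynamics
     L01 -0.688 -1.037 -0.470     0.330 converging
     L02 -0.661 -0.931 -0.444     0.356 converging
     ...
     L10 -0.625 -0.846 -0.334     0.823 converging

hierarchical mean D: -0.661 [-0.847, -0.513]
fitted equilibrium vs observed mean frequency: Pearson r = 0.996
```

Every locality shows a credibly negative `D` (a rare-morph advantage
pulling the frequency toward `p̂ = −α/D`), each is classified
"converging" from the −1 < D < 0 rule, and the fitted equilibria track
the observed long-run mean frequencies almost perfectly (r = 0.996).
Point estimates of `D` from ~20-year series run conservative (too
negative) by up to ~0.1 — a small-sample property of Δp-on-p regressions
discussed in `docs/methods.md`.

The `examples/` directory holds one short script per capability:
simulation + D estimation, closed-form theory curves, the drift null and
Fisher combination, transplant fitness functions, and the
heterozygote-excess test.  A thin CLI mirrors the pipeline stages
(`nfdstools simulate | estimate-d | theory-curves | test-dampening |
drift-null | fit-fitness | fit-advantage | het-test | run-all`), each
accepting `--seed`.

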