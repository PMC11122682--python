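# Methods

`nfdstools` analyses replicated time series of discrete morph frequencies
for the signature of negative frequency-dependent selection (NFDS), and
supports that analysis with transplant-experiment models, drift-null
simulations, and a heterozygote-excess test.  This note documents the
models, the defaults and why they were chosen, the numerical machinery,
and what the synthetic-data generator does and does not emulate.

## The NFDS model and the parameter D

For a morph at frequency `p` with an internal equilibrium `p̂`, the
linearised per-generation change under NFDS is

    Δp = D (p − p̂),        D < 0 under NFDS.

`D` is the slope of Δp on p near the equilibrium.  Its magnitude fixes the
expected deterministic dynamics: gradual convergence for −1 < D < 0,
dampened oscillations for −2 < D < −1, a constant-amplitude two-cycle at
D = −2, and diverging oscillations for D < −2; D > 0 is positive frequency
dependence.  `classify_dynamics` implements exactly these ranges, with a
1e−9 tolerance for the boundary values and the boundaries 0 and −1 folded
into the converging class (the theory states open intervals only; a total,
deterministic classification needs a convention, and it is logged).

`theory.py` also provides the standard drift-free single-generation
changes for overdominance/underdominance
(`Δp = p(1−p)[s2 − p(s1+s2)]`), directional selection
(`Δp = s·p(1−p)[p + h(1−2p)]`), and mainland-island migration
(`Δp = m(p_m − p)`), for comparing the Δp-vs-p shapes that different
processes produce.

## Estimating D from count time series

The observational unit is a locality-by-year-by-host morph count table.
Stripe frequency is measured among pattern-scored individuals (striped vs.
green); the melanic morph is excluded from the dynamics because it does
not take part in the stripe/green fluctuation.  Hosts are pooled within a
locality for D estimation.  Localities qualify when they have at least 10
pairs of consecutive years (configurable); missing years break the Δp
chain and nothing is imputed.

The hierarchical model:

    y_jt ~ Binomial(n_jt, p_jt)                      observed counts
    Δp_jt = p_{j,t+1} − p_jt ~ Normal(α_j + D_j p_jt, σ_j)
    D_j ~ Normal(μ_D, τ_D)

with priors: logit(p_jt) ~ N(0, 1.5), α_j ~ N(0, 1), μ_D ~ N(0, 1),
σ_j and τ_D half-Normal(1).  These are weakly informative on the scales
involved (frequencies, per-generation changes of order 0.1).  The
equilibrium is reported draw-wise as p̂_j = −α_j/D_j (median + 95%
equal-tailed interval), flagged when outside [0, 1].  The regression uses
all (p, Δp) pairs of a locality, not only near-equilibrium points, since
fluctuating series spend most of their time near the equilibrium anyway.

Sampling is by Gibbs-within-Metropolis written for this model: the
(α_j, D_j) block and all hyper-means are conjugate Gaussian draws; scale
parameters use a near-conjugate Inverse-Gamma independence proposal whose
acceptance ratio reduces to the half-Normal prior factor (random-walk
updates on log σ proved sticky when residuals are small); latent logit
frequencies use adaptive random-walk Metropolis in a checkerboard
(even/odd year) schedule, which is exact because a (t, t+1) pair always
couples opposite parities.  Three latent sweeps run per scan.  Multiple
chains are run from dispersed seeds; split-R̂ on every D_j is computed
in-house (cross-checked against `arviz.rhat(method="split")` in the test
suite) and estimation fails loudly above 1.05 unless the caller opts out.
Defaults are 4 chains × (2000 warmup + 2000 draws); the test and
acceptance suites use 2 × (800 + 1000), which the diagnostics show is
sufficient at the problem sizes exercised there.

**Known small-sample bias.** For series of ~20 years the posterior median
of D inherits the classic autoregression small-sample bias (the Hurwicz
bias): even an exactly specified maximum-likelihood estimator on the true
latent frequencies is biased by roughly −0.1 to −0.2 toward stronger NFDS
under stationary fluctuation, and ~−0.05 to −0.1 when series start
displaced from the equilibrium.  This is a property of the estimand at
these series lengths, not of the sampler — a Kalman-filter MLE oracle on
the identical state-space model reproduces it.  Interval coverage is
unaffected (~95% empirically).  Consumers should treat point estimates of
D from short series as conservative (too negative) by up to ~0.1.

Companion analyses: Pearson correlation between fitted p̂ and the observed
mean frequency per locality; ordinary linear regression of p̂ on percent
*Adenostoma*; and a hierarchical binomial model of year-by-host mean
frequencies (cells pooled over localities, logit-normal prior per host)
for descriptive host-specific trajectories.

## Dampening test

If constant NFDS with −1 < D < 0 acted alone, |Δp| would decline over
time.  `test_dampening` fits |Δp_jt| ~ a_j + b_j·(year − start) with both
coefficients hierarchically pooled (Gaussian likelihood, same sampler
family), years from 2000 onward by default, and reports the posterior
probability that each b_j — and the hierarchical mean slope — is negative.
|Δp| is computed from posterior-median latent frequencies (plug-in); this
keeps the test modular, at the cost of ignoring latent uncertainty, and
slightly smooths |Δp| (an attenuation shared by all localities, so the
*trend* test is essentially unaffected).  Year is centered at the filter
start for numerical stability; the fit is exactly invariant to shifting
the year origin together with the filter.

## Drift null

`simulate_null` iterates the fitted deterministic NFDS step followed by
Wright–Fisher binomial sampling of 2·Ne gene copies (Ne defaults to 110,
the system's published contemporary estimate), starting from the observed
initial frequency and running for as many generations as the observed
series has pairs (required for comparable mean |Δp|).  The expected
frequency is clamped to [0, 1] before sampling; fixation needs no special
handling because the NFDS step pulls fixed trajectories back inside
(0, 1) when D < 0.  Each replicate is summarised as the mean absolute
per-generation change; the observed value is compared one-sidedly with
the add-one Monte-Carlo correction p = (k+1)/(reps+1) (with 100 replicates
the smallest attainable p is 1/101 ≈ 0.0099).  Per-locality p-values are
combined by Fisher's method (χ² = −2Σln p, df = 2k).  The Ne sensitivity
analysis repeats everything over a grid (100 down to 20 in steps of 10 by
default) and reports the largest Ne at which a configurable fraction of
localities (default: all) become non-significant — the point at which
drift alone could begin to explain the observed fluctuation.

Calibration measured on synthetic data generated under the null itself:
4.5% false rejection at α = 0.05; power ≈ 0.92 against logit-scale forcing
of SD 0.25 over 15 generations at Ne = 110.

## Transplant-experiment models

The release/recapture design varies the released stripe frequency across
bushes (canonically 0–100% in 5% steps, 20 insects per bush, releases
rounded half-to-even).  Recapture is the survival proxy.

*Fitness function.*  Green recaptures are Binomial(released, q_i) with a
bush-level baseline logit q_i pooled hierarchically (bushes differ);
striped recaptures are Binomial(released, q_i · w(p_i)) where w is the
relative fitness of stripe — linear `a + b p` or a four-parameter logistic
(lower, upper, midpoint, log-steepness) for the step-like alternative.
Relative fitness is by construction invariant to bush-level multiplicative
effects.  Fitting uses an affine-invariant ensemble sampler with a
vectorised log-posterior; models are compared by WAIC on the deviance
scale (per-bush pointwise likelihoods).  The equilibrium is the solution
of w(p) = 1 (closed form for linear, bisection for the logistic), and it
is only *reported* when the fitted frequency effect is credible (95%
interval of b, or of upper − lower, excluding 0) — with a flat function
any noise slope produces a spurious crossing.

*Experiment-level D.*  Δp = p′ − p per bush regressed on the known release
frequency p, with striped recaptures ~ Binomial(total recaptures, p′)
giving binomial uncertainty on the latent p′; a single α and D
(non-hierarchical), wide logit prior (SD 3) on p′ so near-boundary
recapture frequencies are not shrunk toward 0.5.  Bushes that released
only one morph are excluded: their recapture frequency equals the release
frequency structurally and carries no frequency-dependence information.
A residual-preserving joint move on (α, D, latents) keeps this small
sampler well mixed.  Caveat: with a uniform release grid the *linear* Δp
regression is a linearisation of an arch-shaped curve
(Δp = p(1−p)(w−1)/w̄ vanishes at both p = 0 and p = 1), so its zero
crossing −α/D is displaced away from the true equilibrium whenever
p̂ ≠ 0.5 — by construction, independent of selection strength.  The
fitness-function route is the reliable equilibrium estimator from this
design; the D fit is reported for its sign and magnitude near the
equilibrium, not its crossing.

*Morph advantage.*  Recapture ~ morph + block as a hierarchical logistic
model (8 blocks of 10 + 10 in the canonical design); β is the log-odds
advantage of the striped morph, with blocks as zero-centered random
effects.

## Heterozygote excess

Genotype matrices (individuals × SNPs, 0/1/2) are mean-centered, projected
onto the top two principal components (covariance PCA, no scaling), and
clustered by k-means with k = 6, 20 starts, 500 iterations — the six
clusters are the unordered genotype pairs over the green/striped/melanic
structural haplotypes.  Cluster → genotype designation uses externally
supplied phenotype labels (majority vote per cluster) and is pure
relabelling.  Allele frequencies follow from genotype frequencies
(homozygote + half of each involving heterozygote); the Hardy–Weinberg
expected green/striped heterozygote frequency is 2·p_green·p_striped.
The excess test draws `reps` (default 1000) binomial samples of n
individuals at the expected frequency and reports the one-sided fraction
at or above the observed count; ties count toward the tail, and the
add-one correction is the default (a plain k/reps estimator is available).
The Monte-Carlo p converges to the exact binomial upper tail, which is
also exposed (`exact_het_tail`) as a cross-check.

## Synthetic-data generator

`gen_timeseries` evolves each locality's true stripe frequency by the
NFDS step, adds optional exogenous forcing as Normal(0, forcing_sd) noise
on the logit scale (keeps frequencies in (0, 1) without clamping;
forcing_sd = 0 recovers the pure NFDS + drift null exactly), applies
binomial drift at 2·Ne, and then draws observed counts: melanics at an
independent constant frequency (default 0.05 — the melanic morph does not
fluctuate or respond to NFDS), the remainder split striped/green at the
current true frequency.  Defaults mirror the long-term field design: 10
localities × 14 consecutive years, ~70 individuals scored per
locality-year, Ne = 110, forcing_sd = 0.15, locality equilibria spread
over 0.25–0.85.  Initial frequencies default to the equilibrium ± 0.2
(alternating sign across localities): populations in this system are
observed away from their equilibria — persistent displacement is the
phenomenon under study — and an at-equilibrium start would also maximise
the small-sample bias discussed above.  Trajectories that hit 0 or 1 are
returned as-is and flagged, never restarted.

What the generator does *not* emulate: spatial structure and gene flow
between localities, observation effort varying across years, host-specific
selection (the host split, when requested, is a random partition of the
sample at a locality-level frequency), overlapping generations, and
SNP-level linkage structure beyond block-wise haplotype profiles.  Passing
recovery tests on these data therefore demonstrate correctness of the
estimators under the stated model, not robustness to those real-data
features.

`gen_experiment` and `gen_genotypes` emulate the transplant design
(binomial recaptures under a chosen fitness function, probabilities
clamped to [0.01, 0.99] with a warning) and the six-cluster genotype
structure (multinomial clusters; optional SNP matrices built from
haplotype-specific allele-frequency profiles so the clusters separate on
PC1/PC2).

## Numerical conventions

All randomness flows from explicit integer seeds through
`numpy.random.default_rng` / `SeedSequence`; the ensemble sampler's
internal state is seeded from the same source, so every fit is a pure
function of (data, settings, seed).  Posterior summaries are medians with
95% equal-tailed intervals.  Boundary conventions: grid release counts
round half-to-even; Monte-Carlo ties count toward the tail; p + Δp is
clamped to [0, 1] wherever it is used as a binomial probability.  The
pipeline writes every output with the seed and a SHA-256 hash of the full
configuration in its header.

## Problem sizes used by the test suite

Unit and acceptance tests run the estimators at reduced but diagnostic-
clean MCMC sizes (2 chains × 800–1500 warmup + 1000–2500 draws) and the
simulation studies at 50 replicate datasets (D recovery), 200 datasets
(drift-null calibration and power), and 10 replicates (oscillation-test
neutrality, field-scale experiment fits).  These sizes were chosen so the
Monte-Carlo error of each checked quantity is small relative to its
asserted tolerance.
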