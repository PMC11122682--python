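"""Are observed fluctuations larger than NFDS + genetic drift can explain?

Simulates a forced (extra-noisy) trajectory, builds the NFDS + drift null
distribution of the mean absolute per-generation frequency change at
Ne = 110, and combines per-locality evidence with Fisher's method.
"""

import numpy as np

import nfdstools as nt

cfg = nt.SimulationConfig(
    n_localities=10,
    years_per_locality=16,
    D_true=-0.48,
    p_eq_true=np.linspace(0.3, 0.8, 10),
    Ne=110,
    forcing_sd=0.25,  # exogenous forcing beyond drift
    sample_size=100,
    seed=3,
)
series, truth = nt.gen_timeseries(cfg)

p_eq_by_loc = dict(zip(sorted(truth["locality"].unique()), cfg.p_eq_true))
p_values, folds = [], []
for loc, g in truth.groupby("locality"):
    p = g.sort_values("year")["p_true"].to_numpy()
    observed = np.mean(np.abs(np.diff(p)))
    null = nt.simulate_null(
        -0.48, p_eq_by_loc[loc], p[0], len(p) - 1, Ne=110, reps=100, seed=4
    )
    pv, fold = nt.compare_observed(null, observed)
    p_values.append(pv)
    folds.append(fold)
    print(f"{loc}: observed mean |dp| = {observed:.3f}, "
          f"fold-excess over drift = {fold:.2f}, P = {pv:.3f}")

chi2, df, p_comb = nt.fisher_combined(p_values)
print(f"\nFisher's combined test: chi2 = {chi2:.2f}, df = {df}, P = {p_comb:.2e}")
print(
    "\nFold-excess > 1 with small per-locality P means the observed\n"
    "year-to-year changes are too large for NFDS plus drift alone -\n"
    "additional forcing (gene flow or other selection) is required."
)
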