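"""Fit the nine spatial/non-spatial models to one location-year and rank them.

Each model shares the fixed genotype-by-tester cell means and differs in its
random design terms and plot-error structure; AIC (on the variance
parameters) ranks them within the location.
"""
import warnings
import pandas as pd
from metgp import (MODEL_IDS, SimulationConfig, adjusted_means, reml_fit,
                   simulate_genetic_values, simulate_marker_panel, simulate_met)

cfg = SimulationConfig(
    n_years=1, locations_per_year=1, trials_per_location=1,
    genotypes_per_trial=60, n_crosses=35, cross_size_range=(2, 2),
    n_markers=100, shared_checks_across_years=0, block_size=8,
    v_row=0.8, v_col=0.8, v_spatial=4.0, v_nugget=1.5,
    rho_row=0.7, rho_col=0.7, seed=5,
)
panel, cm = simulate_marker_panel(cfg)
truth = simulate_genetic_values(panel, cfg, cm)
fb = simulate_met(cfg, panel, truth)
fb = fb[fb["tester"] == "T1"]

rows = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for m in MODEL_IDS:
        fit = reml_fit(fb, m, n_starts=1, check_hessian=False)
        rows.append({"model": m, "logREML": fit.loglik, "AIC": fit.aic,
                     "converged": fit.converged})
tab = pd.DataFrame(rows).set_index("model")
tab["deltaAIC"] = tab["AIC"] - tab["AIC"].min()
print(tab.round(1).to_string())
best = tab["deltaAIC"].idxmin()
print(f"\nbest model by AIC: {best}")
am = adjusted_means(reml_fit(fb, best, n_starts=1, check_hessian=False))
print(am.table.head().round(2).to_string(index=False))
# The field was simulated with row/column trends plus AR(1)xAR(1) errors and
# a nugget, so the richer spatial models should carry the smallest AIC.
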