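"""Generate a small synthetic multi-environment trial and inspect its anatomy.

Builds a family-structured marker panel, true genetic values, and a two-year
alpha-design field book, then prints the structural facts that matter for the
downstream analysis: how many plots, genotypes and crosses there are, and
which check connects the two years.
"""
import numpy as np
from metgp import SimulationConfig, simulate_genetic_values, simulate_marker_panel, simulate_met

cfg = SimulationConfig(
    n_years=2, locations_per_year=3, trials_per_location=1,
    genotypes_per_trial=40, n_crosses=20, cross_size_range=(4, 6),
    n_markers=300, seed=7,
)
panel, cross_map = simulate_marker_panel(cfg)
truth = simulate_genetic_values(panel, cfg, cross_map)
fieldbook = simulate_met(cfg, panel, truth)

print(f"marker panel: {panel.shape[0]} genotypes x {panel.shape[1]} markers, "
      f"{cross_map['cross'].nunique()} crosses")
print(f"field book: {len(fieldbook)} plots over {fieldbook['year'].nunique()} years, "
      f"{fieldbook['location'].nunique()} locations")
shared = set(fieldbook.loc[fieldbook.year == 2009, 'genotype']) & \
         set(fieldbook.loc[fieldbook.year == 2010, 'genotype'])
print(f"check connecting the years: {sorted(map(str, shared))}")
print(f"true genetic variance among entries: "
      f"{truth.values['true_gebv'].var():.2f} (yield units^2)")
# The shared check is the only genotype observed in both years; everything
# else about the years must be reconciled statistically in stage two.
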