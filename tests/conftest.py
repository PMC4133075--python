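"""Shared fixtures: small synthetic datasets and the spatial-AIC simulation batch."""

import warnings

import numpy as np
import pandas as pd
import pytest

from metgp import stage1
from metgp.simulate import (
    SimulationConfig,
    simulate_genetic_values,
    simulate_marker_panel,
    simulate_met,
)


def small_met_config(**overrides) -> SimulationConfig:
    """A compact two-year, three-location MET used across the suite."""
    base = dict(
        n_years=2, locations_per_year=3, trials_per_location=1,
        genotypes_per_trial=40, n_crosses=20, cross_size_range=(4, 6),
        n_markers=300, block_size=8, seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """(config, panel, cross_map, truth, fieldbook) for the compact MET."""
    cfg = small_met_config()
    panel, cross_map = simulate_marker_panel(cfg)
    truth = simulate_genetic_values(panel, cfg, cross_map)
    fieldbook = simulate_met(cfg, panel, truth)
    return cfg, panel, cross_map, truth, fieldbook


def spatial_trial_config(seed: int, **overrides) -> SimulationConfig:
    """One large trial (10 rows x 16 columns per replicate, two replicates)
    with strong row/column trends and a spatially correlated plot error:
    the generating conditions of the two-dimensional nugget model."""
    base = dict(
        n_years=1, locations_per_year=1, trials_per_location=1,
        genotypes_per_trial=156, n_crosses=90, cross_size_range=(2, 2),
        n_markers=50, n_checks=4, shared_checks_across_years=0, block_size=8,
        v_trial=0.0, v_rep=0.2, v_block=0.3, v_row=0.8, v_col=0.8,
        v_spatial=6.0, v_nugget=2.5, rho_row=0.8, rho_col=0.8,
        tester_sd=0.0, location_sd=0.0, year_sd=0.0, target_plot_h2=0.2,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def spatial_aic_sims():
    """AICs of M1/M2/M6/M9 on 30 fields generated under the M9 structure.

    Shared between the stage-one model-recovery property test and the
    acceptance check that row+column models out-fit the baseline.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(30):
            cfg = spatial_trial_config(seed)
            panel, cm = simulate_marker_panel(cfg)
            truth = simulate_genetic_values(panel, cfg, cm)
            fb = simulate_met(cfg, panel, truth)
            fb = fb[fb["tester"] == "T1"]  # one physical trial set
            out = {}
            for m in ("M1", "M2", "M6", "M9"):
                f = stage1.reml_fit(fb, m, n_starts=1, check_hessian=False)
                out[m] = f.aic if f.converged else np.nan
            rows.append(out)
    return pd.DataFrame(rows)
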