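"""Synthetic multi-environment trial (MET) generator.

Emulates the structure of a hybrid rye testcross breeding program: a panel
of S2-type genotypes grouped into full-sib families ("crosses"), evaluated
as testcross hybrids in alpha-design trials with two replicates at several
locations over several years.  Trials within a year share a set of check
genotypes grown in every trial, consecutive years are connected only
through a configurable number of shared checks, and plot errors carry a
separable AR(1) x AR(1) spatial component plus an independent nugget.

The generator exists so that every downstream stage (spatial REML fits,
stage-wise mean integration, genomic prediction) can be exercised and its
parameter recovery verified against known truth without any external data.

Loci are simulated unlinked (no LD); nothing downstream depends on linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .markers import MarkerMatrix


@dataclass
class SimulationConfig:
    """Parameters of the synthetic MET.

    Counts and structure mirror the motivating breeding program: two
    genotyped years, eleven locations per year, three trial series per
    location with ~107 entries each, 349 crosses totalling ~1610 genotypes,
    four checks per year with one check shared between consecutive years,
    and alpha designs with two replicates and blocks nested in replicates.
    Variance components are in squared yield units (dt/ha)^2.
    """

    n_years: int = 2
    locations_per_year: int = 11
    trials_per_location: int = 3
    genotypes_per_trial: int = 107
    n_crosses: int = 349
    cross_size_range: tuple[int, int] = (2, 8)
    n_markers: int = 11285
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0003
    n_checks: int = 4
    shared_checks_across_years: int = 1
    block_size: int = 10
    blocks_per_row: int = 2  # blocks sit side by side within a field row
    # variance components, squared yield units
    v_trial: float = 0.5
    v_rep: float = 0.3
    v_block: float = 0.4
    v_row: float = 0.2
    v_col: float = 0.2
    v_spatial: float = 1.0
    v_nugget: float = 0.5
    rho_row: float = 0.5
    rho_col: float = 0.5
    tester_sd: float = 0.5
    location_sd: float = 1.0
    year_sd: float = 1.0
    target_plot_h2: float = 0.35
    grand_mean: float = 80.0
    border_missing_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.cross_size_range[0] < 1 or self.cross_size_range[0] > self.cross_size_range[1]:
            raise ValueError(f"invalid cross_size_range {self.cross_size_range}")
        for name in ("v_trial", "v_rep", "v_block", "v_row", "v_col", "v_spatial", "v_nugget"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_row", "rho_col"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if not (0.0 < self.target_plot_h2 < 1.0):
            raise ValueError("target_plot_h2 must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.shared_checks_across_years > self.n_checks:
            raise ValueError("cannot share more checks than exist per year")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.blocks_per_row < 1:
            raise ValueError("blocks_per_row must be >= 1")


@dataclass
class Truth:
    """Ground truth of the simulation: per-genotype values and marker effects."""

    values: pd.DataFrame  # columns: genotype, cross, true_gebv
    marker_effects: pd.Series  # index: marker ids, yield units per coded allele


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _check_ids(config: SimulationConfig) -> list[list[str]]:
    """Check genotype ids per year; consecutive years share exactly
    ``shared_checks_across_years`` of them."""
    per_year = []
    counter = 0
    prev: list[str] = []
    for _ in range(config.n_years):
        shared = prev[: config.shared_checks_across_years]
        fresh = []
        for _ in range(config.n_checks - len(shared)):
            counter += 1
            fresh.append(f"CHK{counter:02d}")
        per_year.append(shared + fresh)
        prev = fresh + shared  # rotate so a different check carries forward next
    return per_year


def simulate_marker_panel(config: SimulationConfig) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Family-structured SNP panel plus the genotype -> cross map.

    For each cross two parents are drawn from Hardy-Weinberg proportions at
    population allele frequencies (uniform over ``maf_range``); offspring
    inherit one allele per parent per locus, independently across loci.
    Check genotypes are unrelated individuals drawn directly from the
    population frequencies, each in its own singleton pseudo-cross.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    p = config.n_markers
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    flip = rng.random(p) < 0.5
    freq = np.where(flip, 1.0 - freq, freq)  # random choice of which allele is minor

    lo, hi = config.cross_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_crosses)
    blocks, genos, crosses = [], [], []
    for c, size in enumerate(sizes):
        parents = rng.binomial(2, freq, size=(2, p)).astype(np.int8)  # allele counts 0..2
        gametes1 = rng.binomial(1, parents[0] / 2.0, size=(size, p))
        gametes2 = rng.binomial(1, parents[1] / 2.0, size=(size, p))
        blocks.append((gametes1 + gametes2 - 1).astype(np.int8))
        cross_id = f"C{c + 1:04d}"
        for k in range(size):
            genos.append(f"{cross_id}.{k + 1}")
            crosses.append(cross_id)
    # checks: unrelated individuals, one singleton pseudo-cross each
    all_checks = sorted({c for year in _check_ids(config) for c in year})
    for chk in all_checks:
        blocks.append(rng.binomial(2, freq, size=(1, p)).astype(np.int8) - 1)
        genos.append(chk)
        crosses.append(f"XC-{chk}")

    Z = np.concatenate(blocks, axis=0).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(Z.shape) < config.missing_rate
        Z[mask] = np.nan
    markers = [f"M{m + 1:05d}" for m in range(p)]
    mm = MarkerMatrix(pd.DataFrame(Z, index=genos, columns=markers))
    cross_map = pd.DataFrame({"genotype": genos, "cross": crosses})
    return mm, cross_map


def simulate_genetic_values(
    markers: MarkerMatrix, config: SimulationConfig, cross_map: pd.DataFrame | None = None
) -> Truth:
    """Draw iid normal marker effects scaled to the target plot heritability.

    Effects are scaled so that var(true_gebv) / (var(true_gebv) + v_e) equals
    ``target_plot_h2``, where v_e = v_spatial + v_nugget is the plot error
    variance implied by the configuration.  Missing marker codes count as 0.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    Z = markers.data.fillna(0.0).to_numpy(dtype=float)
    effects = rng.normal(size=Z.shape[1])
    g = Z @ effects
    vg = float(np.var(g))
    if vg <= 0:
        raise ValueError("marker matrix has zero genetic variance; cannot scale effects")
    v_e = config.v_spatial + config.v_nugget
    target = config.target_plot_h2 / (1.0 - config.target_plot_h2) * v_e
    scale = np.sqrt(target / vg)
    effects *= scale
    g *= scale
    if cross_map is not None:
        cross = cross_map.set_index("genotype")["cross"].reindex(markers.genotypes)
    else:
        cross = pd.Series(pd.NA, index=markers.genotypes)
    values = pd.DataFrame(
        {"genotype": markers.genotypes, "cross": cross.to_numpy(), "true_gebv": g}
    )
    return Truth(values=values, marker_effects=pd.Series(effects, index=markers.markers))


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix rho**|i-j| of dimension n."""
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_spatial_surface(
    n_rows: int,
    n_cols: int,
    rho_row: float,
    rho_col: float,
    v_spatial: float,
    v_nugget: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """One draw from N(0, v_spatial AR1(rho_row) x AR1(rho_col) + v_nugget I).

    Returns an (n_rows, n_cols) array of plot errors.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("field dimensions must be >= 1")
    if v_spatial < 0 or v_nugget < 0:
        raise ValueError("variances must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    Lr = np.linalg.cholesky(ar1_corr(n_rows, rho_row) + 1e-12 * np.eye(n_rows))
    Lc = np.linalg.cholesky(ar1_corr(n_cols, rho_col) + 1e-12 * np.eye(n_cols))
    spatial = np.sqrt(v_spatial) * (Lr @ rng.standard_normal((n_rows, n_cols)) @ Lc.T)
    nugget = np.sqrt(v_nugget) * rng.standard_normal((n_rows, n_cols))
    return spatial + nugget


def _layout_blocks(entries: list[str], block_size: int, rng: np.random.Generator):
    """Randomize entries into blocks of ``block_size`` (last block may be
    smaller -> two block sizes within a trial); block b sits in row b,
    plots along columns."""
    order = list(rng.permutation(entries))
    blocks = [order[i : i + block_size] for i in range(0, len(order), block_size)]
    if len(blocks) > 1 and len(blocks[-1]) == 1:
        # avoid singleton blocks: fold the leftover plot into the previous block
        blocks[-2].extend(blocks.pop())
    return blocks


def simulate_met(
    config: SimulationConfig, markers: MarkerMatrix, truth: Truth
) -> pd.DataFrame:
    """Generate the plot-level field book of the full MET.

    Yield = grand mean + year + location + tester + trial + replicate +
    block (+ row + column) effects + true genetic value + spatially
    correlated plot error + nugget.  Each year evaluates a disjoint set of
    entries plus the year's checks; exactly ``shared_checks_across_years``
    checks connect consecutive years.  One "bridge" location per year grows
    every trial under both testers so tester effects are estimable.
    """
    config.validate()
    rng = _rng(config.seed, 3)
    gebv = truth.values.set_index("genotype")["true_gebv"]

    check_sets = _check_ids(config)
    all_checks = {c for year in check_sets for c in year}
    pool = [g for g in markers.genotypes if g not in all_checks]
    need = config.n_years * config.trials_per_location * config.genotypes_per_trial
    if len(pool) < need:
        raise ValueError(
            f"marker panel has {len(pool)} non-check genotypes but the layout needs {need}"
        )
    pool = list(rng.permutation(pool))

    n_entries = config.genotypes_per_trial + config.n_checks
    if n_entries < config.block_size:
        raise ValueError(
            f"genotypes_per_trial incompatible with block structure: "
            f"{n_entries} entries < block_size {config.block_size}"
        )

    year_eff = rng.normal(0.0, config.year_sd, size=config.n_years)
    loc_names = [f"L{s + 1:02d}" for s in range(config.locations_per_year)]
    loc_eff = dict(zip(loc_names, rng.normal(0.0, config.location_sd, size=len(loc_names))))

    records = []
    trial_counter = 0
    for yi in range(config.n_years):
        year = 2009 + yi
        testers = [f"T{2 * yi + 1}", f"T{2 * yi + 2}"]
        tester_eff = dict(zip(testers, rng.normal(0.0, config.tester_sd, size=2)))
        # trial series of this year: fixed genotype subsets shared across locations
        series = []
        for _ in range(config.trials_per_location):
            trial_counter += 1
            sub = pool[: config.genotypes_per_trial]
            del pool[: config.genotypes_per_trial]
            series.append((f"S{trial_counter}", sub))
        for li, loc in enumerate(loc_names):
            # bridge location (first) grows each series under both testers
            testers_here = testers if li == 0 else [testers[li % 2]]
            for tester in testers_here:
                for trial_name, sub in series:
                    entries = sub + check_sets[yi]
                    t_eff = rng.normal(0.0, np.sqrt(config.v_trial))
                    for rep in (1, 2):
                        r_eff = rng.normal(0.0, np.sqrt(config.v_rep))
                        blocks = _layout_blocks(entries, config.block_size, rng)
                        bpr = config.blocks_per_row
                        n_rows_grid = int(np.ceil(len(blocks) / bpr))
                        n_cols_grid = bpr * config.block_size
                        surface = simulate_spatial_surface(
                            n_rows_grid,
                            n_cols_grid,
                            config.rho_row,
                            config.rho_col,
                            config.v_spatial,
                            config.v_nugget,
                            rng,
                        )
                        row_eff = (
                            rng.normal(0.0, np.sqrt(config.v_row), size=n_rows_grid)
                            if config.v_row > 0
                            else np.zeros(n_rows_grid)
                        )
                        col_eff = (
                            rng.normal(0.0, np.sqrt(config.v_col), size=n_cols_grid)
                            if config.v_col > 0
                            else np.zeros(n_cols_grid)
                        )
                        for b, block_entries in enumerate(blocks):
                            b_eff = rng.normal(0.0, np.sqrt(config.v_block))
                            row_ix = b // bpr
                            col_off = (b % bpr) * config.block_size
                            for c, geno in enumerate(block_entries):
                                records.append(
                                    {
                                        "year": year,
                                        "location": loc,
                                        "trial": trial_name,
                                        "tester": tester,
                                        "replicate": rep,
                                        "block": b + 1,
                                        "row": row_ix + 1,
                                        "col": col_off + c + 1,
                                        "genotype": geno,
                                        "is_check": geno in all_checks,
                                        "yield": (
                                            config.grand_mean
                                            + year_eff[yi]
                                            + loc_eff[loc]
                                            + tester_eff[tester]
                                            + t_eff
                                            + r_eff
                                            + b_eff
                                            + row_eff[row_ix]
                                            + col_eff[col_off + c]
                                            + gebv[geno]
                                            + surface[row_ix, col_off + c]
                                        ),
                                    }
                                )
    fieldbook = pd.DataFrame.from_records(records)
    if config.border_missing_frac > 0:
        fieldbook = _delete_border_plots(fieldbook, config.border_missing_frac, rng)
    return fieldbook


def _delete_border_plots(fb: pd.DataFrame, frac: float, rng: np.random.Generator):
    """Non-rectangularity: drop a fraction of border plots of each replicate."""
    drop_idx = []
    for _, grp in fb.groupby(["year", "location", "trial", "tester", "replicate"]):
        border = grp[
            (grp["row"].isin([grp["row"].min(), grp["row"].max()]))
            | (grp["col"].isin([grp["col"].min(), grp["col"].max()]))
        ]
        k = int(np.floor(frac * len(border)))
        if k > 0:
            drop_idx.extend(rng.choice(border.index.to_numpy(), size=k, replace=False))
    return fb.drop(index=drop_idx).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Writers

def write_fieldbook_csv(fieldbook: pd.DataFrame, path) -> None:
    cols = [
        "year", "location", "trial", "tester", "replicate",
        "block", "row", "col", "genotype", "is_check", "yield",
    ]
    fieldbook[cols].to_csv(path, index=False)


def write_cross_map_csv(cross_map: pd.DataFrame, path) -> None:
    cross_map[["genotype", "cross"]].to_csv(path, index=False)


def write_truth_csv(truth: Truth, path) -> None:
    truth.values.to_csv(path, index=False)
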