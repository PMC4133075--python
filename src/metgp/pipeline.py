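"""End-to-end orchestration: simulate -> QC -> stage 1 -> stage 2 -> GP -> select.

The pipeline persists every intermediate artifact (field book, marker
matrix, per-location adjusted means and fit summaries, stage-two means,
per-repetition predictive abilities, selection tables) under an output
directory, so every number in the final report is traceable to a file.
Failures of individual location-year fits are logged as warnings and do
not abort the run; unreadable inputs are fatal.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gp, markers, selection, simulate, stage1, stage2


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``fieldbook``/``markers``/``cross_map`` point at existing CSV
    inputs, or ``simulation`` holds a :class:`~metgp.simulate.SimulationConfig`
    whose synthetic data are generated (and persisted) first.  The master
    ``seed`` fans out deterministically to the simulator and the CV plans.
    """

    out_dir: str = "metgp-run"
    fieldbook: str | None = None
    markers: str | None = None
    marker_format: str = "csv"
    cross_map: str | None = None
    simulation: simulate.SimulationConfig | None = None
    models: tuple[str, ...] = stage1.MODEL_IDS
    approach: str = "1a"  # year adjustment: 1a, 1b or 2
    cv_k: int = 5
    cv_t: int = 5
    cv_scheme: str = "WC"
    maf_min: float = 0.01
    max_missing: float = 0.10
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.approach not in ("1a", "1b", "2"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.cv_scheme not in ("WC", "AC"):
            raise ValueError(f"unknown CV scheme {self.cv_scheme!r}")
        bad = [m for m in self.models if m not in stage1.MODEL_IDS]
        if bad:
            raise ValueError(f"unknown models: {bad}")
        if not self.models:
            raise ValueError("model list is empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = simulate.SimulationConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    """Bundle of everything a run produced (all persisted under out_dir)."""

    config: PipelineConfig
    fieldbook: pd.DataFrame
    qc_report: markers.QCReport | None
    stage1_means: dict  # (year, loc) -> {model: AdjustedMeans}
    aic_table: pd.DataFrame
    stage2_means: dict  # model -> stage-2 genotype means table
    gp_results: dict  # model -> gp.GPResult
    comparison: selection.ComparisonResult | None
    heritability: dict  # year -> stage2.HeritabilityResult


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and persist intermediates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ----- inputs (simulated or loaded) ------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        panel, cross_map = simulate.simulate_marker_panel(sim)
        truth = simulate.simulate_genetic_values(panel, sim, cross_map)
        fieldbook = simulate.simulate_met(sim, panel, truth)
        simulate.write_fieldbook_csv(fieldbook, out / "fieldbook.csv")
        markers.write_markers(panel, out / "markers.csv")
        simulate.write_cross_map_csv(cross_map, out / "cross_map.csv")
        simulate.write_truth_csv(truth, out / "truth.csv")
    else:
        if not config.fieldbook or not config.markers:
            raise ValueError("need fieldbook and marker paths (or a simulation config)")
        fieldbook = pd.read_csv(config.fieldbook)
        panel = markers.load_markers(config.markers, fmt=config.marker_format)
        cross_map = pd.read_csv(config.cross_map) if config.cross_map else None

    # ----- marker QC -------------------------------------------------------
    panel_qc, qc_report = markers.qc_filter(panel, config.maf_min, config.max_missing)
    qc_report.to_json(out / "qc_report.json")
    Z = markers.encode_for_gp(panel_qc)

    # ----- stage 1: per location-year, per model ---------------------------
    fits = stage1.fit_location_year(fieldbook, models=config.models,
                                    n_starts=config.n_starts)
    stage1_means: dict = {}
    for key, per_model in fits.items():
        stage1_means[key] = {}
        year, loc = key
        stage1.write_fit_summary(per_model, out / f"stage1_{year}_{loc}_fits.json")
        for m, f in per_model.items():
            if not f.converged:
                warnings.warn(f"{m} did not converge for {key}; skipped downstream")
                continue
            am = stage1.adjusted_means(f)
            stage1_means[key][m] = am
            am.table.to_csv(out / f"stage1_{year}_{loc}_{m}_means.csv", index=False)
            np.savetxt(out / f"stage1_{year}_{loc}_{m}_vcov.txt", am.vcov)
    aic_table = stage1.delta_aic_table(fits)
    aic_table.to_csv(out / "delta_aic.csv")

    # ----- stage 2 + GP per model dataset ----------------------------------
    stage2_means: dict = {}
    gp_results: dict = {}
    heritability: dict = {}
    for m in config.models:
        try:
            records = _stage2_for_model(m, stage1_means, config, heritability)
        except ValueError as exc:
            if config.approach == "2" and "common check" in str(exc):
                raise  # disconnected years are a fatal contract violation
            warnings.warn(f"stage 2 failed for {m}: {exc}")
            continue
        if records is None:
            continue
        stage2_means[m] = records
        records.to_csv(out / f"stage2_means_{m}.csv", index=False)
        usable = records[records["genotype"].isin(Z.index)]
        if usable["genotype"].nunique() < 2 * config.cv_k:
            warnings.warn(f"{m}: too few genotyped entries for {config.cv_k}-fold CV")
            continue
        plan = gp.make_folds(sorted(usable["genotype"].unique()),
                             scheme=config.cv_scheme, k=config.cv_k, t=config.cv_t,
                             seed=config.seed, cross_map=cross_map)
        res = gp.run_gp_cv(usable, Z, plan, approach=config.approach)
        gp_results[m] = res
        res.per_repetition.to_csv(out / f"gp_cv_{m}.csv", index=False)

    comparison = None
    if len(gp_results) >= 2:
        rho = pd.DataFrame({m: r.per_repetition.set_index("repetition")["rho"]
                            for m, r in gp_results.items()})
        comparison = selection.compare_models_paired(rho)
        with open(out / "comparison.json", "w") as fh:
            json.dump({"means": comparison.means.to_dict(),
                       "letters": comparison.letters,
                       "alpha": comparison.alpha}, fh, indent=2)

    result = PipelineResult(
        config=config, fieldbook=fieldbook, qc_report=qc_report,
        stage1_means=stage1_means, aic_table=aic_table,
        stage2_means=stage2_means, gp_results=gp_results,
        comparison=comparison, heritability=heritability,
    )
    (out / "report.txt").write_text(write_report(result))
    return result


def _stage2_for_model(model, stage1_means, config, heritability_out):
    """Stage-two genotype means for one model's stage-one dataset."""
    pooled = []
    for (year, loc), per_model in stage1_means.items():
        if model not in per_model:
            continue
        am = per_model[model]
        t = am.table.copy()
        t["year"], t["location"] = year, loc
        t["weight"] = stage2.smith_weights(am).to_numpy()
        pooled.append(t)
    if not pooled:
        return None
    pooled = pd.concat(pooled, ignore_index=True)

    if config.approach in ("1a", "1b"):
        parts = []
        for year, grp in pooled.groupby("year"):
            s2 = stage2.fit_yearwise(grp, grp["weight"], n_starts=config.n_starts)
            parts.append(s2.table)
            if model == config.models[0] and year not in heritability_out:
                heritability_out[year] = stage2.adhoc_heritability(
                    grp, grp["weight"], n_starts=config.n_starts)
        yearly = pd.concat(parts, ignore_index=True)
        if config.approach == "1b":
            yearly = stage2.correct_year_means(yearly)
            yearly["value"] = yearly["mean_corrected"]
        else:
            yearly["value"] = yearly["mean"]
        return yearly  # "weight" holds the stage-2 Smith weights
    # approach 2: one across-years fit
    s2 = stage2.fit_across_years(pooled, n_starts=config.n_starts)
    t = s2.table.copy()
    t["value"] = t["mean"]
    return t


def write_report(result: PipelineResult) -> str:
    """Human-readable run summary: delta-AIC, abilities, heritability."""
    if not result.config.models:
        raise ValueError("no models in the run")
    lines = ["metgp pipeline report", "=" * 60, ""]
    lines.append("Delta-AIC by location-year (0 = best converged model)")
    lines.append(result.aic_table.round(1).to_string())
    lines.append("")
    if result.gp_results:
        lines.append(f"Predictive abilities ({result.config.cv_scheme} sampling, "
                     f"{result.config.cv_k}-fold x {result.config.cv_t})")
        for m, r in result.gp_results.items():
            lines.append(f"  {m}: rho = {r.mean_rho:.3f}  bias = {r.mean_bias:.3f}")
        lines.append("")
    if result.comparison is not None:
        lines.append("Paired comparison (letters: shared = not significantly different)")
        for m in result.comparison.means.index:
            lines.append(f"  {m}: {result.comparison.means[m]:.3f}  "
                         f"{result.comparison.letters[m]}")
        lines.append("")
    if result.heritability:
        lines.append("Ad hoc heritability by year (baseline dataset)")
        for year, h in sorted(result.heritability.items()):
            lines.append(f"  {year}: h2 = {h.h2:.2f}  (sqrt = {np.sqrt(h.h2):.2f})")
    return "\n".join(lines) + "\n"
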