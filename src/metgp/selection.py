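"""Model selection across and within locations, and final model comparison.

Two selection criteria are supported per location-year: the AIC of the
first-stage REML fit (smaller is better) and the genomic-prediction
cross-validation predictive ability rho-GP-CV (larger is better).  Counting
"best fits" over location-years identifies a single model across locations
(strategy one); picking the winner per location builds the mixed datasets
Mix1 (best AIC per location) and Mix2 (best rho-GP-CV per location)
(strategy two).  Final predictive abilities of competing models are
compared with paired t-tests treating each CV repetition as a block, and
summarised by a compact letter display.

The published summary tables of the motivating rye study ship as CSV
resources (delta-AIC per location-year, rho-GP-CV with repeatabilities, and
final predictive abilities) for use as worked-example fixtures.  The
transcripts carry the published best-model markers: where printed values
tie at table precision, the marker preserves the higher-precision ordering
of the source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .gp import make_folds, run_gp_cv
from .stage1 import MODEL_IDS

_MODELS = list(MODEL_IDS)


@dataclass
class SelectionTable:
    """Per location-year model scores with convergence annotations."""

    values: pd.DataFrame  # index (year, location), columns models
    criterion: str  # "aic" (delta-AIC, argmin) or "rho" (argmax)
    best: pd.Series | None = None  # recorded best-model sets, if published
    nonpd: pd.Series | None = None  # models with a non-PD Hessian per row
    extra: pd.DataFrame | None = None  # e.g. repeatability column


def _load_table(name: str, criterion: str, extra_cols=()) -> SelectionTable:
    with resources.files("metgp.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    df = df.set_index(["year", "location"])
    models = [m for m in _MODELS if m in df.columns]
    parse_set = lambda s: set() if pd.isna(s) or s == "" else set(str(s).split(";"))
    best = df["best"].map(parse_set)
    nonpd = df["nonpd"].map(parse_set)
    nonconv = df["nonconverged"].map(parse_set)
    values = df[models].astype(float)
    # published non-converged cells are already empty; assert consistency
    for (ix, mods) in nonconv.items():
        for m in mods:
            assert np.isnan(values.loc[ix, m])
    extra = df[list(extra_cols)] if extra_cols else None
    return SelectionTable(values=values, criterion=criterion, best=best,
                          nonpd=nonpd, extra=extra)


def load_published_delta_aic() -> SelectionTable:
    """Published delta-AIC per model and location-year (fixture)."""
    return _load_table("published_delta_aic.csv", "aic")


def load_published_gpcv() -> SelectionTable:
    """Published rho-GP-CV per model and location-year, with repeatability."""
    return _load_table("published_rho_gpcv.csv", "rho", extra_cols=("repeatability",))


def load_published_abilities() -> pd.DataFrame:
    """Published final predictive abilities under WC and AC sampling."""
    with resources.files("metgp.data").joinpath("published_final_abilities.csv").open() as fh:
        return pd.read_csv(fh, index_col="model")


def _eligible(row: pd.Series, nonpd: set) -> pd.Series:
    """Models eligible to be 'best': converged (non-missing) and PD-Hessian."""
    keep = row.dropna()
    return keep[~keep.index.isin(nonpd)]


def _row_best(row: pd.Series, criterion: str, nonpd: set) -> set:
    elig = _eligible(row, nonpd)
    if elig.empty:
        return set()
    if criterion == "rho" and (elig < 0).all():
        return set()  # negative throughout: no model predicts at all
    target = elig.min() if criterion == "aic" else elig.max()
    return set(elig[elig == target].index)


def count_best_fits(table: SelectionTable, use_recorded_best: bool = True):
    """Count best fits per model over location-years.

    AIC rows are won by the minimum, rho rows by the maximum; exact ties
    count for every tied model; non-converged and non-PD fits are never
    best; rho rows that are negative throughout are excluded from counting.
    When the table carries recorded best markers (published transcripts)
    and ``use_recorded_best`` is true, those markers are counted instead,
    preserving the source's sub-precision tie resolution.  Percentages are
    relative to the number of table rows.

    Returns (counts, percentages) as Series over the table's models.
    """
    values = table.values
    if values.empty:
        raise ValueError("empty selection table")
    models = list(values.columns)
    counts = pd.Series(0, index=models, dtype=int)
    for ix, row in values.iterrows():
        nonpd = table.nonpd.get(ix, set()) if table.nonpd is not None else set()
        computed = _row_best(row, table.criterion, nonpd)
        recorded = table.best.get(ix, set()) if table.best is not None else set()
        if not computed:
            best = set()  # e.g. all-negative rho rows stay excluded from counting
        elif use_recorded_best and recorded:
            best = recorded
        else:
            best = computed
        for m in best:
            counts[m] += 1
    pct = 100.0 * counts / len(values)
    return counts, pct


def select_best(table: SelectionTable, fallback: str = "M1") -> pd.Series:
    """Single winning model per location-year for building Mix datasets.

    Exact ties break toward the simpler model (lower model index); rho rows
    with all-negative abilities fall back to the baseline model.
    """
    choice = {}
    for ix, row in table.values.iterrows():
        nonpd = table.nonpd.get(ix, set()) if table.nonpd is not None else set()
        best = _row_best(row, table.criterion, nonpd)
        if not best:
            choice[ix] = fallback
        else:
            choice[ix] = sorted(best, key=lambda m: int(m.lstrip("M")))[0]
    out = pd.Series(choice, name="model")
    out.index = table.values.index
    return out


def build_mix_dataset(
    means_by_model: dict[str, pd.DataFrame], table: SelectionTable, fallback: str = "M1"
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble a location-specific best-model dataset (Mix1 or Mix2).

    ``means_by_model`` maps model id to its stage-one adjusted means with
    ``year`` and ``location`` columns.  Returns the concatenated means and
    the per-location provenance map.
    """
    provenance = select_best(table, fallback=fallback)
    parts = []
    for (year, loc), model in provenance.items():
        if model not in means_by_model:
            raise ValueError(f"no adjusted means available for {model} at {year}/{loc}")
        df = means_by_model[model]
        part = df[(df["year"] == year) & (df["location"] == loc)]
        if part.empty:
            raise ValueError(f"adjusted means for {model} lack rows for {year}/{loc}")
        parts.append(part.assign(source_model=model))
    return pd.concat(parts, ignore_index=True), provenance


def gpcv_per_location(
    means_by_location: dict[tuple, dict[str, pd.DataFrame]],
    Z: pd.DataFrame,
    k: int = 5,
    t: int = 5,
    seed: int = 0,
    scheme: str = "WC",
    cross_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """rho-GP-CV per location-year and model.

    ``means_by_location`` maps (year, location) to {model: adjusted-means
    DataFrame with genotype, mean, se}.  The fold plan for a location is
    built once from a fixed seed and reused for every model, so models are
    compared on identical training/validation splits.  Locations with
    fewer than 2k marker-genotyped entries are skipped with a warning.
    """
    rows = {}
    for key, per_model in sorted(means_by_location.items()):
        genos = None
        for df in per_model.values():
            g = [x for x in df["genotype"] if x in Z.index]
            genos = g if genos is None else genos
        if genos is None or len(genos) < 2 * k:
            warnings.warn(f"location {key}: fewer than {2 * k} genotyped entries; skipped")
            continue
        plan = make_folds(sorted(set(genos)), scheme=scheme, k=k, t=t, seed=seed,
                          cross_map=cross_map)
        rows[key] = {}
        for model, df in per_model.items():
            df = df[df["genotype"].isin(Z.index)]
            recs = pd.DataFrame({
                "genotype": df["genotype"].to_numpy(),
                "value": df["mean"].to_numpy(float),
                "weight": 1.0 / np.maximum(df["se"].to_numpy(float), 1e-12) ** 2,
            })
            res = run_gp_cv(recs, Z, plan, approach="2")
            rows[key][model] = res.mean_rho
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.names = ["year", "location"]
    return out


# ---------------------------------------------------------------------------
# Paired comparison with compact letter display


@dataclass
class ComparisonResult:
    means: pd.Series  # per-model mean predictive ability
    p_values: pd.DataFrame  # pairwise paired-t p-values
    letters: dict[str, str]  # compact letter display
    alpha: float


def _paired_p(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        # degenerate paired t: constant differences
        return 0.0 if abs(d.mean()) > 0 else 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def compact_letter_display(models, significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Models share a letter iff they are not significantly different; the
    relation is reflexive and symmetric and every model receives at least
    one letter.
    """
    groups: list[set] = [set(models)]
    for (a, b) in sorted(significant):
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    # stable letter order: by first model appearance
    order = {m: i for i, m in enumerate(models)}
    groups.sort(key=lambda g: min(order[m] for m in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {m: "" for m in models}
    for li, g in enumerate(groups):
        for m in models:
            if m in g:
                letters[m] += alphabet[li % len(alphabet)]
    return letters


def compare_models_paired(rho_by_model: pd.DataFrame, alpha: float = 0.05) -> ComparisonResult:
    """All-pairs paired t-tests on per-repetition predictive abilities.

    ``rho_by_model`` has one row per CV repetition (the blocking factor)
    and one column per model.  Zero-variance paired differences are flagged
    degenerate and declared significant iff the constant difference is
    non-zero.
    """
    if rho_by_model.shape[0] < 2:
        raise ValueError("need at least two CV repetitions for the paired t-test")
    models = list(rho_by_model.columns)
    P = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
    sig = set()
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            p = _paired_p(rho_by_model[a].to_numpy(float), rho_by_model[b].to_numpy(float))
            P.loc[a, b] = P.loc[b, a] = p
            if p < alpha:
                sig.add((a, b))
    letters = compact_letter_display(models, sig)
    return ComparisonResult(means=rho_by_model.mean(), p_values=P,
                            letters=letters, alpha=alpha)
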