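"""First-stage spatial analysis of single location-year field data.

Nine candidate mixed models (M1..M9) share the same fixed part -- cell means
for every observed genotype x tester combination -- and differ in their
random design terms and residual plot-error structure:

==== =============================== ======================================
id   random terms                    residual structure
==== =============================== ======================================
M1   trial, rep, block               independent (ID)
M2   trial, rep, block, row, column  ID
M3   trial, rep, block               AR(1) within block
M4   trial, rep, block               linear variance within block + nugget
M5   trial, rep, block               AR(1) x AR(1) within replicate
M6   trial, rep, block, row, column  AR(1) x AR(1) within replicate
M7   trial, rep, block               M3 + nugget
M8   trial, rep, block               M5 + nugget
M9   trial, rep, block, row, column  M6 + nugget
==== =============================== ======================================

Replicates are nested in trials, blocks in replicates, and row/column
effects in replicates.  All models are fitted by REML; since the fixed part
is identical across M1..M9, they are compared by AIC computed on the number
of variance parameters only.  Distances are integer plot-index differences
(unit plot spacing); one residual structure is shared by all trials of a
location-year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import (
    AR1Residual,
    AR1xAR1Residual,
    IDResidual,
    LVResidual,
    MixedModel,
    REMLFit,
    indicator_matrix,
)

MODEL_IDS = tuple(f"M{i}" for i in range(1, 10))

# model id -> (has row/column random effects, residual kind, nugget)
_MODEL_TABLE = {
    "M1": (False, "id", False),
    "M2": (True, "id", False),
    "M3": (False, "ar1_block", False),
    "M4": (False, "lv_block", True),  # LV includes a nugget by definition
    "M5": (False, "ar1xar1_rep", False),
    "M6": (True, "ar1xar1_rep", False),
    "M7": (False, "ar1_block", True),
    "M8": (False, "ar1xar1_rep", True),
    "M9": (True, "ar1xar1_rep", True),
}


@dataclass
class ModelSpec:
    """Term list and residual structure of one first-stage model."""

    model_id: str
    random_terms: tuple[str, ...]
    residual: str
    nugget: bool

    @property
    def needs_coordinates(self) -> bool:
        return self.residual != "id" or "row" in self.random_terms


def build_model_spec(model_id: str) -> ModelSpec:
    """Model definition for one of M1..M9."""
    if model_id not in _MODEL_TABLE:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    rowcol, residual, nugget = _MODEL_TABLE[model_id]
    terms = ("trial", "replicate", "block") + (("row", "col") if rowcol else ())
    return ModelSpec(model_id=model_id, random_terms=terms, residual=residual, nugget=nugget)


@dataclass
class Stage1Fit:
    """REML solution for one model on one location-year."""

    model_id: str
    fit: REMLFit
    cells: pd.DataFrame = field(repr=False)  # genotype, tester per fixed column
    data: pd.DataFrame = field(repr=False)

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def hessian_pd(self) -> bool:
        return self.fit.hessian_pd

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def varcomp(self) -> dict[str, float]:
        return dict(self.fit.params)

    def summary(self) -> dict:
        return {
            "model": self.model_id,
            "logREML": self.loglik,
            "AIC": self.aic,
            "n_varparams": self.fit.n_varparams,
            "converged": self.converged,
            "hessian_pd": self.hessian_pd,
            "varcomp": self.varcomp,
        }


@dataclass
class AdjustedMeans:
    """Stage-one adjusted genotype-by-tester means with their covariance."""

    table: pd.DataFrame  # genotype, tester, (location, year,) mean, se
    vcov: np.ndarray

    def __post_init__(self):
        d = np.diag(self.vcov)
        se2 = self.table["se"].to_numpy() ** 2
        if not np.allclose(d, se2, rtol=1e-8, atol=1e-12):
            raise ValueError("SE^2 must equal the vcov diagonal")


def _required_columns(data: pd.DataFrame, spec: ModelSpec) -> None:
    needed = {"genotype", "tester", "trial", "replicate", "block", "yield"}
    if spec.needs_coordinates:
        needed |= {"row", "col"}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"field book lacks columns required by {spec.model_id}: {sorted(missing)}")


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Fixed design (GT cell means), random-term designs, residual structure."""
    cells = data[["genotype", "tester"]].astype(str).agg(":".join, axis=1)
    cell_levels = pd.unique(cells)
    X = indicator_matrix(cells)
    cell_df = pd.DataFrame(
        [lvl.split(":", 1) for lvl in cell_levels], columns=["genotype", "tester"]
    )

    def nested(*cols):
        return data[list(cols)].astype(str).agg(":".join, axis=1)

    # the physical trial is the (series x tester) unit: a genotype subset
    # grown under both testers occupies two separate field trials
    trial = nested("trial", "tester")
    rep = nested("trial", "tester", "replicate")
    block = nested("trial", "tester", "replicate", "block")
    randoms = {
        "trial": indicator_matrix(trial),
        "replicate": indicator_matrix(rep),
        "block": indicator_matrix(block),
    }
    if "row" in spec.random_terms:
        randoms["row"] = indicator_matrix(nested("trial", "tester", "replicate", "row"))
        randoms["col"] = indicator_matrix(nested("trial", "tester", "replicate", "col"))

    if spec.residual == "id":
        residual = IDResidual(len(data))
    elif spec.residual == "ar1_block":
        residual = AR1Residual(block, data["col"], nugget=spec.nugget)
    elif spec.residual == "lv_block":
        residual = LVResidual(block, data["col"])
    elif spec.residual == "ar1xar1_rep":
        residual = AR1xAR1Residual(rep, data["row"], data["col"], nugget=spec.nugget)
    else:  # pragma: no cover
        raise ValueError(spec.residual)
    return X, cell_df, randoms, residual


def reml_fit(
    data: pd.DataFrame, model_id: str, n_starts: int = 3, tol: float = 1e-8,
    check_hessian: bool = True,
) -> Stage1Fit:
    """Fit one of M1..M9 to a single location-year field book by REML.

    Optimizer failures are reported through the ``converged`` /
    ``hessian_pd`` flags of the result, never raised.
    """
    spec = build_model_spec(model_id)
    _required_columns(data, spec)
    data = data.reset_index(drop=True)
    X, cell_df, randoms, residual = _design(data, spec)
    if X.shape[1] >= len(data):
        raise ValueError(
            f"{len(data)} plots cannot support {X.shape[1]} genotype-by-tester cells"
        )
    model = MixedModel(data["yield"], X, random_terms=randoms, residual=residual)
    fit = model.fit(n_starts=n_starts, tol=tol, check_hessian=check_hessian)
    return Stage1Fit(model_id=model_id, fit=fit, cells=cell_df, data=data)


def aic(fit: Stage1Fit) -> float:
    return fit.aic


def delta_aic_table(fits_by_row: dict[tuple, dict[str, Stage1Fit]]) -> pd.DataFrame:
    """Delta-AIC table: rows = location-year, columns = models.

    Delta-AIC is relative to the best *converged* model of each row;
    non-converged models appear as missing.
    """
    if not fits_by_row:
        raise ValueError("no fits supplied")
    rows = {}
    for key, fits in fits_by_row.items():
        aics = {m: f.aic for m, f in fits.items() if f.converged and np.isfinite(f.aic)}
        if not aics:
            raise ValueError(f"no converged model for {key}")
        best = min(aics.values())
        rows[key] = {m: aics.get(m, np.nan) - best for m in fits}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.names = ["year", "location"] if out.index.nlevels == 2 else out.index.names
    return out


def adjusted_means(sfit: Stage1Fit) -> AdjustedMeans:
    """BLUEs of the genotype-by-tester cells with full covariance matrix.

    With cell-means coding the fixed design has one column per observed
    cell, so every observed cell is estimable; the BLUE vector is
    (X' V^-1 X)^- X' V^-1 y and its covariance (X' V^-1 X)^-.
    """
    if not sfit.converged:
        warnings.warn(f"adjusted means from a non-converged {sfit.model_id} fit")
    beta, C = sfit.fit.beta, sfit.fit.vcov_beta
    table = sfit.cells.copy()
    table["mean"] = beta
    table["se"] = np.sqrt(np.clip(np.diag(C), 0.0, None))
    for col in ("location", "year"):
        if col in sfit.data.columns:
            vals = sfit.data[col].unique()
            if len(vals) == 1:
                table[col] = vals[0]
    return AdjustedMeans(table=table, vcov=C)


def fit_location_year(
    fieldbook: pd.DataFrame,
    models=MODEL_IDS,
    n_starts: int = 3,
    check_hessian: bool = True,
) -> dict[tuple, dict[str, Stage1Fit]]:
    """Fit a set of models to every location-year of a field book.

    Per-fit failures are logged as warnings and flagged, not raised.
    """
    out: dict[tuple, dict[str, Stage1Fit]] = {}
    for (year, loc), grp in fieldbook.groupby(["year", "location"]):
        out[(year, loc)] = {}
        for m in models:
            try:
                out[(year, loc)][m] = reml_fit(
                    grp, m, n_starts=n_starts, check_hessian=check_hessian
                )
            except ValueError as exc:
                warnings.warn(f"{m} failed for {year}/{loc}: {exc}")
    return out


def write_fit_summary(fits: dict[str, Stage1Fit], path) -> None:
    with open(path, "w") as fh:
        json.dump({m: f.summary() for m, f in fits.items()}, fh, indent=2, default=float)
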