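"""Second-stage integration of adjusted means across locations and testers.

Stage-one genotype-by-tester means enter a weighted mixed model whose
residual variance is *fixed* from the first stage rather than estimated:

* Year-wise model (Approach 1): for each year, mean_{hsv} = G_h + T_v +
  L_s + (GL)_{hs} + (GT)_{hv} + (LT)_{sv} + (GLT)_{hsv} + e_{hsv}, with
  genotype and tester fixed, everything containing location random, and
  var(e_{hsv}) pinned to 1/w_{hsv} where w is the Smith weight (diagonal
  of the inverse of the stage-one variance-covariance matrix).  The
  within-year genotype BLUEs are M2; Approach 1b additionally subtracts
  the simple per-year mean of all genotype means (M2*), Approach 1a
  forwards M2 and fits year as a fixed effect in the prediction stage.

* Across-years model (Approach 2): genotype fixed, year-by-tester cells
  fixed (the year main effect is absorbed by them and can be dropped),
  all interactions containing year or location random, residual variance
  pinned to the squared standard errors of the year-wise stage.  Years
  are connected only through shared check genotypes; disconnected year
  sets are a hard error.

The module also provides the ad hoc heritability h2 = s2_g / (s2_g +
vbar_delta / 2) -- with vbar_delta the mean variance of a difference of
two genotype BLUEs -- and the within-location repeatability
R = s2_GT / (s2_GT + s2_R + s2_B + s2_e) (trial variance excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import FixedResidual, IDResidual, MixedModel, indicator_matrix
from .stage1 import AdjustedMeans, Stage1Fit, reml_fit


@dataclass
class Stage2Means:
    """Genotype means leaving the second stage (per year or across years)."""

    table: pd.DataFrame  # genotype, (year,) mean, se, weight
    vcov: np.ndarray | None = None  # BLUE covariance of the genotype means


@dataclass
class HeritabilityResult:
    sigma2_g: float
    vbar_delta: float
    h2: float


@dataclass
class RepeatabilityResult:
    sigma2_gt: float
    sigma2_rep: float
    sigma2_block: float
    sigma2_e: float
    repeatability: float
    flagged: bool = False


def smith_weights(means: AdjustedMeans) -> pd.Series:
    """Smith weights: diagonal of the inverse stage-one vcov.

    Singular covariance matrices fall back to the Moore-Penrose
    pseudo-inverse with a warning.
    """
    V = np.asarray(means.vcov, float)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("stage-1 vcov singular; using pseudo-inverse for Smith weights")
        Vi = np.linalg.pinv(V)
    w = np.diag(Vi).copy()
    if np.any(w <= 0):
        warnings.warn("non-positive Smith weights clipped")
        w = np.clip(w, 1e-10, None)
    return pd.Series(w, index=means.table.index, name="weight")


def _smith_from_vcov(C: np.ndarray) -> np.ndarray:
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        warnings.warn("singular BLUE vcov; pseudo-inverse used for weights")
        Ci = np.linalg.pinv(C)
    return np.clip(np.diag(Ci), 1e-10, None)


def _genotype_blues(fit, gl_levels: np.ndarray, extra_contrast_cols: int):
    """Genotype means averaged over the non-genotype fixed contrasts."""
    n_g = len(gl_levels)
    L = np.zeros((n_g, n_g + extra_contrast_cols))
    L[:, :n_g] = np.eye(n_g)
    if extra_contrast_cols:
        L[:, n_g:] = 1.0 / (extra_contrast_cols + 1)  # average over all levels
    est, C = fit.estimable(L)
    return est, (C + C.T) / 2


def _contrasts(levels) -> tuple[np.ndarray, list]:
    """Treatment-coded contrasts (first level dropped)."""
    Z = indicator_matrix(levels)
    names = list(pd.unique(np.asarray(levels, dtype=object)))
    return Z[:, 1:], names[1:]


def fit_yearwise(
    means: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    n_starts: int = 3,
) -> Stage2Means:
    """Approach 1 second stage for one year.

    ``means`` needs columns genotype, tester, location, mean; ``weights``
    aligns with its rows.  Returns per-genotype BLUEs with SEs and the
    inverse-squared-SE weights forwarded to the prediction stage.
    """
    df = means.reset_index(drop=True)
    w = np.asarray(weights, float).ravel()
    if len(w) != len(df):
        raise ValueError("weights do not align with means")
    Xg = indicator_matrix(df["genotype"])
    genos = list(pd.unique(df["genotype"].astype(object)))
    Xt, _ = _contrasts(df["tester"])
    X = np.hstack([Xg, Xt])

    randoms = {}
    if df["location"].nunique() > 1:
        randoms["L"] = indicator_matrix(df["location"])
        randoms["GL"] = indicator_matrix(df[["genotype", "location"]].astype(str).agg(":".join, axis=1))
        randoms["LT"] = indicator_matrix(df[["location", "tester"]].astype(str).agg(":".join, axis=1))
    if df["tester"].nunique() > 1:
        randoms["GT"] = indicator_matrix(df[["genotype", "tester"]].astype(str).agg(":".join, axis=1))
    randoms["GLT"] = np.eye(len(df))  # one cell per mean: extra residual-type variance

    R0 = np.diag(1.0 / w)
    model = MixedModel(df["yield"] if "yield" in df else df["mean"], X,
                       random_terms=randoms, residual=FixedResidual(len(df)), R0=R0)
    fit = model.fit(n_starts=n_starts)
    est, C = _genotype_blues(fit, np.array(genos), Xt.shape[1])
    se = np.sqrt(np.clip(np.diag(C), 0.0, None))
    table = pd.DataFrame({"genotype": genos, "mean": est, "se": se})
    # Smith weights from the BLUE vcov: shared uncertainty (e.g. the location
    # main effect common to every mean) cancels between genotypes and must not
    # inflate the fixed error variances handed to the prediction stage.
    table["weight"] = _smith_from_vcov(C)
    if "year" in df.columns and df["year"].nunique() == 1:
        table.insert(1, "year", df["year"].iloc[0])
    return Stage2Means(table=table, vcov=C)


def _year_connectivity(df: pd.DataFrame) -> None:
    years = sorted(df["year"].unique())
    sets = {y: set(df.loc[df["year"] == y, "genotype"]) for y in years}
    reached = {years[0]}
    frontier = [years[0]]
    while frontier:
        y = frontier.pop()
        for z in years:
            if z not in reached and sets[y] & sets[z]:
                reached.add(z)
                frontier.append(z)
    missing = [y for y in years if y not in reached]
    if missing:
        raise ValueError(
            f"years {missing} share no genotype with year {years[0]}; "
            "the across-years model needs at least one common check"
        )


def fit_across_years(means: pd.DataFrame, n_starts: int = 3) -> Stage2Means:
    """Approach 2 second stage: one model across all years.

    ``means`` needs columns genotype, tester, location, year, mean, se.
    Residual variances are fixed at se**2 (inverse-squared-SE weighting);
    year-by-tester cells are fixed, the year main effect is dropped, and
    all interactions containing year or location are random.
    """
    df = means.reset_index(drop=True)
    if df["year"].nunique() < 2:
        raise ValueError("across-years integration needs at least two years")
    _year_connectivity(df)

    Xg = indicator_matrix(df["genotype"])
    genos = list(pd.unique(df["genotype"].astype(object)))
    at = df[["year", "tester"]].astype(str).agg(":".join, axis=1)
    Xat, _ = _contrasts(at)
    X = np.hstack([Xg, Xat])

    def cross(*cols):
        return indicator_matrix(df[list(cols)].astype(str).agg(":".join, axis=1))

    randoms = {}
    if df["location"].nunique() > 1:
        randoms["L"] = cross("location")
        randoms["GL"] = cross("genotype", "location")
        randoms["LA"] = cross("location", "year")
        randoms["LAT"] = cross("location", "year", "tester")
        randoms["GLA"] = cross("genotype", "location", "year")
    randoms["GA"] = cross("genotype", "year")
    randoms["GAT"] = cross("genotype", "year", "tester")
    randoms["GLAT"] = np.eye(len(df))

    R0 = np.diag(df["se"].to_numpy(float) ** 2)
    model = MixedModel(df["mean"], X, random_terms=randoms,
                       residual=FixedResidual(len(df)), R0=R0)
    fit = model.fit(n_starts=n_starts)
    est, C = _genotype_blues(fit, np.array(genos), Xat.shape[1])
    se = np.sqrt(np.clip(np.diag(C), 0.0, None))
    table = pd.DataFrame({"genotype": genos, "mean": est, "se": se})
    table["weight"] = 1.0 / np.maximum(se, 1e-12) ** 2
    return Stage2Means(table=table, vcov=C)


def correct_year_means(yearwise: pd.DataFrame) -> pd.DataFrame:
    """Approach 1b year correction: subtract the simple per-year mean.

    The correction uses the unweighted mean over the complete set of
    genotype means of each year, so corrected means average exactly zero
    within every year.
    """
    df = yearwise.copy()
    year_mean = df.groupby("year")["mean"].transform("mean")
    df["mean_corrected"] = df["mean"] - year_mean
    return df


def heritability(sigma2_g: float, vbar_delta: float) -> float:
    """Ad hoc heritability h2 = s2_g / (s2_g + vbar_delta / 2)."""
    if sigma2_g < 0 or vbar_delta < 0:
        raise ValueError("variances must be >= 0")
    denom = sigma2_g + vbar_delta / 2.0
    return 0.0 if denom == 0 else sigma2_g / denom


def mean_variance_of_difference(vcov: np.ndarray) -> float:
    """Average var(g_h - g_h') over all ordered pairs h != h'."""
    C = np.asarray(vcov, float)
    n = C.shape[0]
    if n < 2:
        raise ValueError("need at least two genotypes")
    s1 = np.trace(C)
    s2 = C.sum()
    return float(2.0 * (n * s1 - s2) / (n * (n - 1)))


def adhoc_heritability(
    means: pd.DataFrame, weights, n_starts: int = 3
) -> HeritabilityResult:
    """Heritability of one year from the second-stage model.

    The genetic variance comes from a genotype-random refit of the
    year-wise model; vbar_delta from the BLUE covariance of the
    genotype-fixed fit.
    """
    fixed = fit_yearwise(means, weights, n_starts=n_starts)
    vdelta = mean_variance_of_difference(fixed.vcov)

    df = means.reset_index(drop=True)
    w = np.asarray(weights, float).ravel()
    Xt, _ = _contrasts(df["tester"])
    X = np.hstack([np.ones((len(df), 1)), Xt])
    randoms = {"G": indicator_matrix(df["genotype"])}
    if df["location"].nunique() > 1:
        randoms["L"] = indicator_matrix(df["location"])
        randoms["GL"] = indicator_matrix(df[["genotype", "location"]].astype(str).agg(":".join, axis=1))
        randoms["LT"] = indicator_matrix(df[["location", "tester"]].astype(str).agg(":".join, axis=1))
    if df["tester"].nunique() > 1:
        randoms["GT"] = indicator_matrix(df[["genotype", "tester"]].astype(str).agg(":".join, axis=1))
    randoms["GLT"] = np.eye(len(df))
    model = MixedModel(df["mean"], X, random_terms=randoms,
                       residual=FixedResidual(len(df)), R0=np.diag(1.0 / w))
    fit = model.fit(n_starts=n_starts)
    s2g = max(fit.params.get("G", 0.0), 0.0)
    if s2g <= 1e-8:
        warnings.warn("genetic variance estimated at zero; h2 = 0")
        s2g = 0.0
    return HeritabilityResult(sigma2_g=s2g, vbar_delta=vdelta,
                              h2=heritability(s2g, vdelta))


def repeatability_from_components(
    v_gt: float, v_rep: float, v_block: float, v_e: float
) -> float:
    """R = between-group variance over total phenotypic variance.

    Trial variance is excluded from the denominator.
    """
    total = v_gt + v_rep + v_block + v_e
    if total == 0:
        raise ValueError("all variance components are zero; repeatability undefined")
    return v_gt / total


def repeatability(fieldbook: pd.DataFrame, n_starts: int = 3) -> RepeatabilityResult:
    """Within-location repeatability from a genotype-random baseline refit.

    Refits the baseline first-stage model with the genotype-by-tester term
    random on one location-year's plots.
    """
    df = fieldbook.reset_index(drop=True)

    def nested(*cols):
        return df[list(cols)].astype(str).agg(":".join, axis=1)

    randoms = {
        "GT": indicator_matrix(nested("genotype", "tester")),
        "trial": indicator_matrix(nested("trial", "tester")),
        "replicate": indicator_matrix(nested("trial", "tester", "replicate")),
        "block": indicator_matrix(nested("trial", "tester", "replicate", "block")),
    }
    model = MixedModel(df["yield"], np.ones((len(df), 1)),
                       random_terms=randoms, residual=IDResidual(len(df)))
    fit = model.fit(n_starts=n_starts)
    comp = [max(fit.params[k], 0.0) for k in ("GT", "replicate", "block", "sigma2_e")]
    flagged = sum(comp) == 0
    r = 0.0 if flagged else repeatability_from_components(*comp)
    if flagged:
        warnings.warn("all repeatability components zero; R undefined")
    return RepeatabilityResult(
        sigma2_gt=comp[0], sigma2_rep=comp[1], sigma2_block=comp[2],
        sigma2_e=comp[3], repeatability=r, flagged=flagged,
    )
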