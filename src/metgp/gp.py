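"""Genomic prediction by ridge-regression BLUP (RR-BLUP) with k-fold CV.

The model for the vector of second-stage genotype means y is

    y = X b + Z u + e,   u ~ N(0, s2_u I_p),   e ~ N(0, R)

with Z the n x p matrix of coded marker scores and R a *fixed* diagonal
error covariance whose entries are the inverses of the stage-two weights.
Estimation runs on the equivalent genomic-kernel form var(y) = s2 Gamma + R
with Gamma = Z Z' / p (the rescaling Z* = Z / sqrt(p) leaves the genetic
values Z u invariant after rescaling s2_u), which needs a single REML
variance parameter.  Marker effects are back-solved from the kernel fit,
so RR-BLUP and the kernel (GBLUP) route agree identically.

Cross-validation supports two sampling schemes over a family-structured
panel: "WC" (within crosses -- plain random partition of genotypes) and
"AC" (across crosses -- whole full-sib families are kept together in one
fold), with a fixed master seed so fold plans are reproducible and
identical across the model datasets being compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .reml import FixedResidual, IDResidual, MixedModel, indicator_matrix


@dataclass
class GPModel:
    """Fitted RR-BLUP model."""

    beta: np.ndarray
    marker_effects: pd.Series  # original {-1,0,1} code space
    sigma2_g: float  # variance of the genomic kernel term (Gamma scale)
    loglik: float
    converged: bool
    gebv: pd.Series  # training records
    marker_ids: list = field(repr=False, default=None)


@dataclass
class FoldPlan:
    """k x t cross-validation plan: genotype -> fold per repetition."""

    scheme: str
    k: int
    assignments: list[dict]  # one dict per repetition
    seed: int

    @property
    def t(self) -> int:
        return len(self.assignments)


@dataclass
class GPResult:
    """Per-repetition predictive abilities and bias of one CV run."""

    per_repetition: pd.DataFrame  # repetition, rho, bias
    predictions: pd.DataFrame  # repetition, genotype, predicted, observed

    @property
    def mean_rho(self) -> float:
        return float(self.per_repetition["rho"].mean())

    @property
    def mean_bias(self) -> float:
        return float(self.per_repetition["bias"].mean())


def _reml_sigma2(y, X, R_diag, G):
    """REML of var(y) = s2 * G + diag(R_diag) via the whitened eigenbasis."""
    w = 1.0 / np.sqrt(R_diag)
    Gt = G * np.outer(w, w)
    lam, U = linalg.eigh((Gt + Gt.T) / 2)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ (w * y)
    Xr = U.T @ (w[:, None] * X)
    log_det_w2 = float(np.sum(np.log(R_diag)))  # log|W^-2| term restoring scale

    def negll(log_s2):
        s2 = np.exp(log_s2)
        d = s2 * lam + 1.0
        Xd = Xr / d[:, None]
        XtVX = Xr.T @ Xd
        sign, ldx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtVX, Xd.T @ yr)
        r = yr - Xr @ beta
        quad = float(yr @ (yr / d) - (Xd.T @ yr) @ beta)
        ldV = float(np.sum(np.log(d))) + log_det_w2
        return 0.5 * (ldV + ldx + quad)

    res = optimize.minimize_scalar(negll, bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x)), -float(res.fun), bool(res.success)


def rrblup_fit(
    y,
    R_diag,
    X,
    Z: pd.DataFrame,
    genotype_index=None,
    sigma2_g: float | None = None,
) -> GPModel:
    """Fit RR-BLUP to phenotypic records.

    Parameters
    ----------
    y : phenotypic records (one per row of ``Z``).
    R_diag : fixed residual variances (inverse stage-two weights).
    X : fixed design (intercept; plus year indicators under Approach 1a).
    Z : coded marker matrix aligned with the records (rows may repeat a
        genotype's marker vector if it has several records).
    sigma2_g : if given, the kernel-scale genetic variance is fixed at this
        value instead of estimated by REML (mixed-model equations only).
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    marker_ids = list(Z.columns) if isinstance(Z, pd.DataFrame) else None
    idx = genotype_index if genotype_index is not None else (
        Z.index if isinstance(Z, pd.DataFrame) else pd.RangeIndex(len(y))
    )
    Zm = np.asarray(Z, float)
    n, p = Zm.shape
    if n != len(y):
        raise ValueError("records and marker rows do not align")
    if p < 1 or not np.any(Zm):
        raise ValueError("marker matrix is empty or all-zero")
    R_diag = np.asarray(R_diag, float).ravel()
    if np.any(R_diag <= 0):
        raise ValueError("R diagonal entries must be > 0")

    G = Zm @ Zm.T / p  # Gamma = Z* Z*' with Z* = Z / sqrt(p)
    if sigma2_g is not None:
        s2, ll, ok = float(sigma2_g), np.nan, True
    else:
        s2, ll, ok = _reml_sigma2(y, X, R_diag, G)

    V = s2 * G + np.diag(R_diag)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.pinv(XtViX) @ (X.T @ Vi @ y)
    resid = y - X @ beta
    # u* = s2 Z*' V^-1 r in the rescaled space; original-code effects u = u*/sqrt(p)
    u = s2 * (Zm.T @ (Vi @ resid)) / p
    gebv = Zm @ u
    return GPModel(
        beta=beta,
        marker_effects=pd.Series(u, index=marker_ids),
        sigma2_g=s2,
        loglik=ll,
        converged=ok,
        gebv=pd.Series(gebv, index=idx),
        marker_ids=marker_ids,
    )


def gebv_predict(model: GPModel, Z_new: pd.DataFrame) -> pd.Series:
    """GEBVs for new genotypes: g = Z_new @ u (same code space as training)."""
    if isinstance(Z_new, pd.DataFrame):
        if model.marker_ids is not None and list(Z_new.columns) != model.marker_ids:
            raise ValueError("marker columns of Z_new do not match the training matrix")
        return pd.Series(Z_new.to_numpy(float) @ model.marker_effects.to_numpy(),
                         index=Z_new.index)
    Zn = np.asarray(Z_new, float)
    if Zn.shape[1] != len(model.marker_effects):
        raise ValueError("marker dimension mismatch")
    return pd.Series(Zn @ model.marker_effects.to_numpy())


# ---------------------------------------------------------------------------
# Cross-validation


def make_folds(
    genotypes,
    scheme: str = "WC",
    k: int = 5,
    t: int = 5,
    seed: int = 0,
    cross_map: pd.DataFrame | None = None,
) -> FoldPlan:
    """Build a k-fold x t-repetition CV plan.

    WC partitions genotypes uniformly at random into k near-equal folds.
    AC assigns whole crosses to folds by a seeded randomized greedy rule
    (shuffled crosses go one by one to the currently smallest fold), so no
    cross is ever split.  The same seed yields the identical plan whatever
    dataset or model it is later applied to.
    """
    genotypes = list(genotypes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if scheme not in ("WC", "AC"):
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    if scheme == "AC":
        if cross_map is None:
            raise ValueError("AC sampling requires a cross map")
        cm = cross_map.set_index("genotype")["cross"]
        missing = [g for g in genotypes if g not in cm.index]
        if missing:
            raise ValueError(f"genotypes without cross assignment: {missing[:5]}")
        by_cross: dict = {}
        for g in genotypes:
            by_cross.setdefault(cm[g], []).append(g)
        if k > len(by_cross):
            raise ValueError(f"k={k} folds but only {len(by_cross)} crosses")
    assignments = []
    for rep in range(t):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        if scheme == "WC":
            perm = rng.permutation(len(genotypes))
            folds = np.array_split(perm, k)
            a = {}
            for f, ix in enumerate(folds):
                for i in ix:
                    a[genotypes[i]] = f
        else:
            names = list(by_cross)
            order = rng.permutation(len(names))
            counts = np.zeros(k, dtype=int)
            a = {}
            for ci in order:
                f = int(np.argmin(counts))  # smallest fold; ties -> lowest index
                for g in by_cross[names[ci]]:
                    a[g] = f
                counts[f] += len(by_cross[names[ci]])
        assignments.append(a)
    return FoldPlan(scheme=scheme, k=k, assignments=assignments, seed=seed)


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predicted GEBVs and observations.

    Not adjusted by the square root of heritability.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn("zero variance; predictive ability undefined")
        return np.nan
    return float(stats.pearsonr(predicted, observed)[0])


def prediction_bias(observed, predicted) -> float:
    """Bias as the OLS slope of observed on predicted (1 = unbiased)."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if np.std(predicted) == 0:
        warnings.warn("zero variance in predictions; bias undefined")
        return np.nan
    return float(stats.linregress(predicted, observed).slope)


def run_gp_cv(
    records: pd.DataFrame,
    Z: pd.DataFrame,
    plan: FoldPlan,
    approach: str = "2",
) -> GPResult:
    """k-fold cross-validated genomic prediction.

    ``records`` needs columns genotype, value, weight (and year when
    ``approach`` is "1a", in which case year indicators join the fixed
    design and observations are corrected by the training-fit year effects
    before correlating).  One predictive ability and one bias slope are
    computed per repetition over the concatenated validation folds.
    """
    df = records.reset_index(drop=True)
    known = set(Z.index)
    drop = ~df["genotype"].isin(known)
    if drop.any():
        warnings.warn(f"{int(drop.sum())} records without marker data skipped")
        df = df[~drop].reset_index(drop=True)
    year_levels = sorted(df["year"].unique()) if approach == "1a" else []
    rows, preds = [], []
    for rep, assign in enumerate(plan.assignments):
        pred_all, obs_all, geno_all = [], [], []
        for fold in range(plan.k):
            vs_mask = df["genotype"].map(lambda g: assign.get(g, -1) == fold)
            ts = df[~vs_mask]
            vs = df[vs_mask]
            if vs.empty or len(ts) < 3:
                continue
            X_ts = _design_matrix(ts, year_levels)
            model = rrblup_fit(
                ts["value"].to_numpy(),
                1.0 / ts["weight"].to_numpy(float),
                X_ts,
                Z.loc[ts["genotype"]],
            )
            g_hat = gebv_predict(model, Z.loc[vs["genotype"]])
            obs = vs["value"].to_numpy(float)
            if approach == "1a":
                # subtract the year part of the training fixed-effect fit
                X_vs = _design_matrix(vs, year_levels)
                obs = obs - X_vs[:, 1:] @ model.beta[1:]
            pred_all.extend(np.asarray(g_hat))
            obs_all.extend(obs)
            geno_all.extend(vs["genotype"])
        rho = predictive_ability(pred_all, obs_all)
        bias = prediction_bias(obs_all, pred_all)
        rows.append({"repetition": rep, "rho": rho, "bias": bias})
        preds.append(pd.DataFrame({"repetition": rep, "genotype": geno_all,
                                   "predicted": pred_all, "observed": obs_all}))
    return GPResult(per_repetition=pd.DataFrame(rows),
                    predictions=pd.concat(preds, ignore_index=True))


def _design_matrix(df: pd.DataFrame, year_levels) -> np.ndarray:
    X = [np.ones((len(df), 1))]
    # treatment coding against the first year level
    for y in year_levels[1:]:
        X.append((df["year"] == y).to_numpy(float)[:, None])
    return np.hstack(X)


# ---------------------------------------------------------------------------
# Variance decompositions


def cross_share(sigma2_g: float, sigma2_c: float, sigma2_e: float) -> float:
    """Share of the total variation attributed to crosses, in percent."""
    total = sigma2_g + sigma2_c + sigma2_e
    if total <= 0:
        raise ValueError("total variance must be positive")
    return 100.0 * sigma2_c / total


@dataclass
class CrossDecomposition:
    sigma2_g: float
    sigma2_c: float
    sigma2_e: float
    share_pct: float
    genotype_confounded: bool  # True when no genotype has repeated records


def cross_decomposition(
    means: pd.DataFrame, cross_map: pd.DataFrame, n_starts: int = 3
) -> CrossDecomposition:
    """Genotype/cross variance decomposition of second-stage means.

    Fits mean = intercept + genotype + cross + error with genotype and
    cross random.  With a single record per genotype the genotype and
    error variances are confounded (only their sum and the cross variance
    are identified); the result carries a flag in that case.  The cross
    share uses the total of all three components.
    """
    df = means.reset_index(drop=True)
    cm = cross_map.set_index("genotype")["cross"]
    missing = set(df["genotype"]) - set(cm.index)
    if missing:
        raise ValueError(f"genotypes without cross assignment: {sorted(missing)[:5]}")
    crosses = df["genotype"].map(cm)
    if crosses.nunique() < 2:
        raise ValueError("cross variance inestimable with a single cross")
    randoms = {"G": indicator_matrix(df["genotype"]), "C": indicator_matrix(crosses)}
    model = MixedModel(df["mean"], np.ones((len(df), 1)),
                       random_terms=randoms, residual=IDResidual(len(df)))
    fit = model.fit(n_starts=n_starts)
    vg = max(fit.params["G"], 0.0)
    vc = max(fit.params["C"], 0.0)
    ve = max(fit.params["sigma2_e"], 0.0)
    confounded = bool(df["genotype"].value_counts().max() == 1)
    return CrossDecomposition(
        sigma2_g=vg, sigma2_c=vc, sigma2_e=ve,
        share_pct=cross_share(vg, vc, ve),
        genotype_confounded=confounded,
    )


def marker_share(sigma2_marker: float, sigma2_polygenic: float) -> float:
    """Percent of total genetic variance captured by the marker term."""
    total = sigma2_marker + sigma2_polygenic
    if total <= 0:
        raise ValueError("total genetic variance must be positive")
    return 100.0 * sigma2_marker / total


@dataclass
class PolygenicPartition:
    sigma2_marker: float
    sigma2_polygenic: float
    marker_share_pct: float
    converged: bool


def polygenic_partition(
    y, R_diag, X, Z: pd.DataFrame, relationship: np.ndarray | None = None,
    n_starts: int = 3,
) -> PolygenicPartition:
    """Marker + polygenic variance split of the prediction model.

    Extends var(y) = s2_m Gamma + R with a second genotype-level random
    effect of covariance ``relationship`` (identity by default) and
    reports the marker-captured share of the total genetic variance.
    """
    y = np.asarray(y, float).ravel()
    Zm = np.asarray(Z, float)
    n, p = Zm.shape
    G = Zm @ Zm.T / p
    K = np.eye(n) if relationship is None else np.asarray(relationship, float)
    ev_min = linalg.eigvalsh((K + K.T) / 2).min()
    if ev_min < -1e-8 * max(1.0, abs(ev_min)):
        raise ValueError("relationship matrix is not positive semi-definite")
    model = MixedModel(y, X, random_terms={"marker": G, "polygenic": K},
                       residual=FixedResidual(n), R0=np.diag(np.asarray(R_diag, float)))
    fit = model.fit(n_starts=n_starts)
    vm = max(fit.params["marker"], 0.0)
    vp = max(fit.params["polygenic"], 0.0)
    return PolygenicPartition(
        sigma2_marker=vm, sigma2_polygenic=vp,
        marker_share_pct=marker_share(vm, vp) if vm + vp > 0 else np.nan,
        converged=fit.converged,
    )
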