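"""Dense REML machinery for Gaussian linear mixed models.

Fits models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, R(theta) + R0)

by maximising the restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

over transformed variance parameters (log for variances, atanh for
correlations).  ``R0`` is an optional *fixed* error covariance (used for
stage-two fits where the residual variance of an adjusted mean is pinned to
the inverse of its Smith weight), and ``R(theta)`` is a parametric residual
structure (identity, AR(1), AR(1)xAR(1), linear variance, with or without a
nugget).

Everything here is dense numpy/scipy linear algebra; problem sizes in this
package are at most a few thousand observations per fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize

# Transformed-parameter bounds: variances live on a log scale, correlations
# on an atanh scale clipped at |rho| <= 0.999.
_LOG_VAR_LO, _LOG_VAR_HI = -14.0, 14.0
_RHO_MAX = 0.999
_ATANH_HI = np.arctanh(_RHO_MAX)
_BIG = 1e10


def indicator_matrix(levels: Sequence) -> np.ndarray:
    """0/1 design matrix for a factor, one column per observed level."""
    codes, _ = _factorize(levels)
    n, q = len(codes), codes.max() + 1
    Z = np.zeros((n, q))
    Z[np.arange(n), codes] = 1.0
    return Z


def _factorize(levels):
    import pandas as pd

    codes, uniques = pd.factorize(np.asarray(levels, dtype=object))
    if (codes < 0).any():
        raise ValueError("factor levels contain missing values")
    return codes, uniques


class ResidualStructure:
    """Protocol for parametric residual covariances.

    Subclasses expose ``param_kinds`` (ordered ``(name, kind)`` with kind in
    {"var", "corr"}) and ``build(params) -> (n, n) ndarray``.
    """

    param_kinds: tuple[tuple[str, str], ...] = ()

    def build(self, params: dict[str, float]) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class FixedResidual(ResidualStructure):
    """No free residual parameters (error covariance fully fixed via R0)."""

    param_kinds = ()

    def __init__(self, n: int):
        self.n = n

    def build(self, params):
        return np.zeros((self.n, self.n))


class IDResidual(ResidualStructure):
    param_kinds = (("sigma2_e", "var"),)

    def __init__(self, n: int):
        self.n = n

    def build(self, params):
        return params["sigma2_e"] * np.eye(self.n)


def _group_blocks(groups):
    codes, _ = _factorize(groups)
    order = {}
    for i, c in enumerate(codes):
        order.setdefault(c, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


class AR1Residual(ResidualStructure):
    """One-dimensional AR(1) correlation within groups (blocks).

    corr(i, j) = rho**|pos_i - pos_j| for plots in the same group, zero
    across groups; an optional nugget adds sigma2_nugget * I.
    """

    def __init__(self, groups, positions, nugget: bool = False):
        self.blocks = _group_blocks(groups)
        self.pos = np.asarray(positions, dtype=float)
        self.n = len(self.pos)
        kinds = [("sigma2_e", "var"), ("rho", "corr")]
        if nugget:
            kinds.append(("sigma2_nugget", "var"))
        self.param_kinds = tuple(kinds)
        self.nugget = nugget

    def build(self, params):
        R = np.zeros((self.n, self.n))
        s, rho = params["sigma2_e"], params["rho"]
        for ix in self.blocks:
            d = np.abs(self.pos[ix, None] - self.pos[None, ix])
            R[np.ix_(ix, ix)] = s * rho ** d
        if self.nugget:
            R += params["sigma2_nugget"] * np.eye(self.n)
        return R


class AR1xAR1Residual(ResidualStructure):
    """Separable row x column AR(1) within groups (replicates).

    corr = rho_row**|dr| * rho_col**|dc| for plots in the same group; the
    full-grid Kronecker structure restricted to the observed plots, so
    non-rectangular layouts are handled by construction.
    """

    def __init__(self, groups, rows, cols, nugget: bool = False):
        self.blocks = _group_blocks(groups)
        self.rows = np.asarray(rows, dtype=float)
        self.cols = np.asarray(cols, dtype=float)
        self.n = len(self.rows)
        kinds = [("sigma2_e", "var"), ("rho_row", "corr"), ("rho_col", "corr")]
        if nugget:
            kinds.append(("sigma2_nugget", "var"))
        self.param_kinds = tuple(kinds)
        self.nugget = nugget

    def build(self, params):
        R = np.zeros((self.n, self.n))
        s = params["sigma2_e"]
        rr, rc = params["rho_row"], params["rho_col"]
        for ix in self.blocks:
            dr = np.abs(self.rows[ix, None] - self.rows[None, ix])
            dc = np.abs(self.cols[ix, None] - self.cols[None, ix])
            R[np.ix_(ix, ix)] = s * rr ** dr * rc ** dc
        if self.nugget:
            R += params["sigma2_nugget"] * np.eye(self.n)
        return R


class LVResidual(ResidualStructure):
    """Linear-variance covariance within groups, with mandatory nugget.

    cov(i, j) = sigma2_lv * (1 - d_ij / d_max) within a block, where d_max
    is the block extent (largest pairwise distance; 1 for singleton blocks),
    plus sigma2_nugget * I on the diagonal.
    """

    param_kinds = (("sigma2_lv", "var"), ("sigma2_nugget", "var"))

    def __init__(self, groups, positions):
        self.blocks = _group_blocks(groups)
        self.pos = np.asarray(positions, dtype=float)
        self.n = len(self.pos)

    def build(self, params):
        R = np.zeros((self.n, self.n))
        s = params["sigma2_lv"]
        for ix in self.blocks:
            d = np.abs(self.pos[ix, None] - self.pos[None, ix])
            dmax = max(d.max(), 1.0)
            R[np.ix_(ix, ix)] = s * (1.0 - d / dmax)
        R += params["sigma2_nugget"] * np.eye(self.n)
        return R


@dataclass
class REMLFit:
    """Result of a restricted-maximum-likelihood fit."""

    loglik: float
    params: dict[str, float]
    beta: np.ndarray
    vcov_beta: np.ndarray
    converged: bool
    hessian_pd: bool
    n_varparams: int
    V: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        """AIC on variance parameters only: -2 logREML + 2 q."""
        return -2.0 * self.loglik + 2.0 * self.n_varparams

    def estimable(self, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Estimates and covariance of linear combinations ``L @ beta``."""
        L = np.atleast_2d(L)
        return L @ self.beta, L @ self.vcov_beta @ L.T


class MixedModel:
    """A Gaussian mixed model to be fitted by REML.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design matrix (rank deficiency handled by pseudo-inverse).
    random_terms : ordered mapping name -> design matrix Z_k (or an (n, n)
        symmetric kernel K_k, detected by shape); one variance per term.
    residual : a :class:`ResidualStructure`; defaults to ``IDResidual``.
    R0 : optional fixed error covariance added to V (e.g. diag(1/w)).
    """

    def __init__(self, y, X, random_terms=None, residual=None, R0=None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = len(self.y)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if np.linalg.matrix_rank(self.X) > n - 1 and residual is None:
            raise ValueError("fewer observations than fixed-effect rank")
        self.kernels: dict[str, np.ndarray] = {}
        for name, Z in (random_terms or {}).items():
            Z = np.asarray(Z, dtype=float)
            if Z.shape == (n, n) and np.allclose(Z, Z.T):
                self.kernels[name] = Z
            else:
                self.kernels[name] = Z @ Z.T
        self.residual = residual if residual is not None else IDResidual(n)
        self.R0 = np.zeros((n, n)) if R0 is None else np.atleast_2d(np.asarray(R0, float))
        self.param_kinds: list[tuple[str, str]] = [
            (name, "var") for name in self.kernels
        ] + list(self.residual.param_kinds)
        if not self.param_kinds and not np.any(self.R0):
            raise ValueError("model has no variance parameters and no fixed R0")

    # -- parameter transforms -------------------------------------------------
    def _to_natural(self, theta: np.ndarray) -> dict[str, float]:
        out = {}
        for (name, kind), t in zip(self.param_kinds, theta):
            out[name] = float(np.exp(t)) if kind == "var" else float(np.tanh(t))
        return out

    def _bounds(self):
        return [
            (_LOG_VAR_LO, _LOG_VAR_HI) if kind == "var" else (-_ATANH_HI, _ATANH_HI)
            for _, kind in self.param_kinds
        ]

    # -- restricted likelihood ------------------------------------------------
    def _build_V(self, params: dict[str, float]) -> np.ndarray:
        V = self.R0.copy()
        for name, K in self.kernels.items():
            V += params[name] * K
        V += self.residual.build({k: params[k] for k, _ in self.residual.param_kinds})
        return V

    def loglik(self, params: dict[str, float]) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        V = self._build_V(params)
        n = len(self.y)
        jitter = 1e-9 * max(np.mean(np.diag(V)), 1e-12)
        try:
            L = linalg.cholesky(V + jitter * np.eye(n), lower=True)
        except linalg.LinAlgError:
            return -np.inf
        ldV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = linalg.cho_solve((L, True), self.y)
        Vi_X = linalg.cho_solve((L, True), self.X)
        XtViX = self.X.T @ Vi_X
        sign, ldXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            # rank-deficient fixed design: use nonzero eigenvalues
            ev = linalg.eigvalsh(XtViX)
            ev = ev[ev > 1e-10 * max(ev.max(), 1.0)]
            ldXVX = float(np.sum(np.log(ev)))
        beta = np.linalg.pinv(XtViX) @ (self.X.T @ Vi_y)
        quad = float(self.y @ Vi_y - (self.X.T @ Vi_y) @ beta)
        return -0.5 * (ldV + ldXVX + quad)

    def _objective(self, theta: np.ndarray) -> float:
        ll = self.loglik(self._to_natural(theta))
        return _BIG if not np.isfinite(ll) else -ll

    def _start_points(self, n_starts: int) -> list[np.ndarray]:
        vy = max(np.var(self.y), 1e-4)
        n_var = sum(1 for _, k in self.param_kinds if k == "var")
        base = []
        for _, kind in self.param_kinds:
            if kind == "var":
                base.append(np.log(vy / max(n_var, 1)))
            else:
                base.append(np.arctanh(0.2))
        base = np.array(base)
        starts = [base]
        # deterministic perturbations; no RNG involved
        for i in range(1, n_starts):
            shift = np.array(
                [((-1) ** (i + j)) * 1.5 * ((i + 1) / 2) for j in range(len(base))]
            )
            starts.append(np.clip(base + shift, -6.0, 6.0))
        return starts

    def fit(self, n_starts: int = 3, tol: float = 1e-8, check_hessian: bool = True) -> REMLFit:
        """Maximise the restricted likelihood with multistart L-BFGS-B."""
        if not self.param_kinds:
            return self._finalize({}, True, True)
        bounds = self._bounds()
        best = None
        converged = False
        for theta0 in self._start_points(n_starts):
            try:
                res = optimize.minimize(
                    self._objective,
                    theta0,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
                )
                if not res.success and np.isfinite(res.fun):
                    # line searches stall near correlation bounds; polish with
                    # a derivative-free pass from the best point found
                    res2 = optimize.minimize(
                        self._objective, res.x, method="Nelder-Mead", bounds=bounds,
                        options={"xatol": 1e-6, "fatol": tol, "maxfev": 800},
                    )
                    if res2.fun <= res.fun:
                        res = res2
            except Exception:  # pragma: no cover - optimizer blowups become flags
                continue
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success) or converged
        if best is None or not np.isfinite(best.fun) or best.fun >= _BIG / 2:
            # flagged failure, not an exception
            nan_params = {name: np.nan for name, _ in self.param_kinds}
            p = self.X.shape[1]
            return REMLFit(
                loglik=-np.inf,
                params=nan_params,
                beta=np.full(p, np.nan),
                vcov_beta=np.full((p, p), np.nan),
                converged=False,
                hessian_pd=False,
                n_varparams=len(self.param_kinds),
            )
        hess_pd = True
        if check_hessian:
            hess_pd = self._hessian_pd(best.x)
        return self._finalize(self._to_natural(best.x), converged, hess_pd)

    def _hessian_pd(self, theta: np.ndarray, step: float = 1e-3) -> bool:
        """Finite-difference Hessian of -logREML at the optimum; PD check.

        Parameters at the boundary of their box (variance pinned at ~0) are
        excluded: a one-sided boundary optimum has no interior curvature.
        """
        free = [
            i
            for i, (lo, hi) in enumerate(self._bounds())
            if theta[i] > lo + 0.5 and theta[i] < hi - 0.5
        ]
        if not free:
            return True
        m = len(free)
        H = np.zeros((m, m))
        f0 = self._objective(theta)
        for a in range(m):
            for b in range(a, m):
                ta = np.array(theta)
                tb = np.array(theta)
                tab = np.array(theta)
                ta[free[a]] += step
                tb[free[b]] += step
                tab[free[a]] += step
                tab[free[b]] += step
                H[a, b] = H[b, a] = (
                    self._objective(tab) - self._objective(ta) - self._objective(tb) + f0
                ) / step**2
        try:
            ev = np.linalg.eigvalsh((H + H.T) / 2)
        except np.linalg.LinAlgError:
            return False
        return bool(ev.min() > -1e-4 * max(abs(ev).max(), 1.0))

    def _finalize(self, params: dict[str, float], converged: bool, hess_pd: bool) -> REMLFit:
        V = self._build_V(params)
        n = len(self.y)
        jitter = 1e-9 * max(np.mean(np.diag(V)), 1e-12)
        for _ in range(6):  # escalate jitter for boundary fits (|rho| ~ 1, no nugget)
            try:
                L = linalg.cholesky(V + jitter * np.eye(n), lower=True)
                break
            except linalg.LinAlgError:
                jitter *= 100.0
        else:
            raise linalg.LinAlgError("fitted covariance matrix is numerically singular")
        Vi_y = linalg.cho_solve((L, True), self.y)
        Vi_X = linalg.cho_solve((L, True), self.X)
        XtViX = self.X.T @ Vi_X
        C = np.linalg.pinv(XtViX)
        beta = C @ (self.X.T @ Vi_y)
        return REMLFit(
            loglik=self.loglik(params),
            params=params,
            beta=beta,
            vcov_beta=(C + C.T) / 2,
            converged=converged,
            hessian_pd=hess_pd,
            n_varparams=len(self.param_kinds),
            V=V,
            X=self.X,
            y=self.y,
        )


def gls_blue(y, X, V) -> tuple[np.ndarray, np.ndarray]:
    """Generalized-least-squares estimates and their covariance for known V."""
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    Vi = np.linalg.inv(V)
    C = np.linalg.pinv(X.T @ Vi @ X)
    return C @ (X.T @ Vi @ y), (C + C.T) / 2
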