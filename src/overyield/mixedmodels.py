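"""Gaussian linear mixed models with a log-linear residual-dispersion submodel.

The model for plot (or tree) i is

    y_i = x_i' beta + sum_g b_{g, level(i)} + e_i,
    b_g ~ N(0, sigma_g^2 I),    e_i ~ N(0, exp(delta_0 + delta_1 * r_i)),

where each grouping g is a set of nested labels (e.g. experiment:composition)
treated as one intercept factor, and r_i is an optional dispersion covariate
(species richness here), so the residual *variance* is log-linear in
richness — the convention of glmmTMB's ``dispformula``. With no dispersion
covariate the residual variance is constant, recovering the ordinary LMM.

Estimation is marginal maximum likelihood: beta is profiled out by GLS at
each variance-parameter value, and the variance parameters
theta = (log sigma_g^2 ..., delta_0[, delta_1]) are optimized numerically.
The marginal covariance V = D + Z G Z' is never formed; all quantities use
the Woodbury identity through the q x q matrix W = G^-1 + Z' D^-1 Z, which
stays small because Z holds only grouped intercepts. ML (not REML) is used
throughout so AIC is comparable across fixed-effect structures.

Wald inference: t statistics with n - p residual degrees of freedom for
fixed effects; normal-approximation standard errors for the dispersion
coefficients from the numerical Hessian of the profile likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp
from scipy import stats

from .errors import ConvergenceError, InvalidInputError, SingularFitWarning

_LOGVAR_MIN, _LOGVAR_MAX = -16.0, 16.0


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed`` lists term strings over numeric columns: a bare column name,
    a power like ``"richness^2"``, or an interaction product like
    ``"richness:wd"``. An intercept is always included. ``groups`` lists the
    random-intercept groupings, each a tuple of label columns concatenated
    into one nested factor. ``dispersion`` names the covariate of the
    log-variance submodel (None = constant variance). ``transform`` is
    ``"identity"`` or ``"log-plus-constant"`` (response becomes
    ``log(y + constant)``; constant defaults to half the smallest positive
    response value).
    """

    response: str
    fixed: tuple[str, ...]
    groups: tuple[tuple[str, ...], ...] = ()
    dispersion: str | None = None
    transform: str = "identity"
    constant: float | None = None

    def __init__(self, response, fixed, groups=(), dispersion=None,
                 transform="identity", constant=None):
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed", tuple(fixed))
        object.__setattr__(self, "groups", tuple(tuple(g) for g in groups))
        object.__setattr__(self, "dispersion", dispersion)
        object.__setattr__(self, "transform", transform)
        object.__setattr__(self, "constant", constant)
        if transform not in {"identity", "log-plus-constant"}:
            raise InvalidInputError(f"unknown transform {transform!r}")


def _eval_factor(data: pd.DataFrame, factor: str) -> np.ndarray:
    name, _, power = factor.partition("^")
    if name not in data.columns:
        raise InvalidInputError(f"column {name!r} not in data")
    col = data[name].to_numpy(dtype=float)
    return col ** int(power) if power else col


def build_design(data: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with intercept; ':' builds products, '^' powers."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for term in terms:
        x = np.ones(n)
        for factor in term.split(":"):
            x = x * _eval_factor(data, factor.strip())
        cols.append(x)
        names.append(term)
    return np.column_stack(cols), names


def _grouping_matrix(data: pd.DataFrame, grouping: tuple[str, ...]) -> tuple[sp.csr_matrix, int]:
    for col in grouping:
        if col not in data.columns:
            raise InvalidInputError(f"grouping column {col!r} not in data")
    labels = data[list(grouping)].astype(str).agg(":".join, axis=1)
    codes, levels = pd.factorize(labels, sort=True)
    q = len(levels)
    n = len(data)
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))
    return Z, q


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Estimates from one mixed-model fit."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    vc: dict[str, float]
    disp_params: pd.Series
    disp_bse: pd.Series
    loglik: float
    aic: float
    nobs: int
    df_resid: int
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    constant: float | None = None
    theta: np.ndarray | None = None
    optimizer_message: str = ""
    _design_terms: tuple[str, ...] = field(default_factory=tuple)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tq = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - tq * self.bse, "upper": self.params + tq * self.bse}
        )

    def predict(self, newdata: pd.DataFrame, transformed: bool = False) -> np.ndarray:
        """Population-level (fixed-effects) prediction; with a log-plus-constant
        response, the default back-transforms to the original scale."""
        X, _ = build_design(newdata, self._design_terms)
        lp = X @ self.params.to_numpy()
        if self.spec.transform == "log-plus-constant" and not transformed:
            return np.exp(lp) - self.constant
        return lp


# ---------------------------------------------------------------------------
# marginal likelihood machinery


class _MarginalML:
    """Profile negative log-likelihood over variance parameters.

    theta layout: [log sigma_g^2 per grouping] + [delta_0] (+ [delta_1] when a
    dispersion covariate is present).
    """

    def __init__(self, y, X, Zs, qs, disp_x):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.Zs = Zs          # list of csr matrices
        self.qs = qs          # levels per grouping
        self.disp_x = disp_x  # covariate vector or None
        self.Z = sp.hstack(Zs, format="csr") if Zs else None
        self.q = int(sum(qs))

    def n_theta(self) -> int:
        return len(self.qs) + 1 + (1 if self.disp_x is not None else 0)

    def _resid_logvar(self, theta) -> np.ndarray:
        k = len(self.qs)
        if self.disp_x is None:
            return np.full(self.n, theta[k])
        return theta[k] + theta[k + 1] * self.disp_x

    def decompose(self, theta):
        """Return (nll, beta, XtVX_inv) at theta."""
        logvar = np.clip(self._resid_logvar(theta), _LOGVAR_MIN, _LOGVAR_MAX)
        inv_d = np.exp(-logvar)
        y, X = self.y, self.X
        Xd = X * inv_d[:, None]
        XtVX = X.T @ Xd
        XtVy = Xd.T @ y
        ytVy = float(y @ (y * inv_d))
        logdet = float(logvar.sum())

        if self.Z is not None:
            ZtDiX = self.Z.T @ Xd                      # q x p dense
            ZtDiy = self.Z.T @ (y * inv_d)
            W = (self.Z.T @ sp.diags(inv_d) @ self.Z).toarray()
            ginv = np.concatenate(
                [np.full(q, math.exp(-theta[i])) for i, q in enumerate(self.qs)]
            )
            W[np.diag_indices_from(W)] += ginv
            try:
                c = sla.cholesky(W, lower=True)
            except sla.LinAlgError:
                return np.inf, None, None
            B = sla.solve_triangular(c, ZtDiX, lower=True)
            alpha = sla.solve_triangular(c, ZtDiy, lower=True)
            XtVX = XtVX - B.T @ B
            XtVy = XtVy - B.T @ alpha
            ytVy = ytVy - float(alpha @ alpha)
            logdet += 2.0 * float(np.log(np.diag(c)).sum())
            logdet += float(sum(q * theta[i] for i, q in enumerate(self.qs)))

        try:
            cx = sla.cho_factor(XtVX)
        except sla.LinAlgError:
            return np.inf, None, None
        beta = sla.cho_solve(cx, XtVy)
        quad = ytVy - float(beta @ XtVy)
        if quad < 0:  # numerical round-off near perfect fit
            quad = 0.0
        nll = 0.5 * (self.n * math.log(2 * math.pi) + logdet + quad)
        return nll, beta, XtVX

    def nll(self, theta) -> float:
        val = self.decompose(theta)[0]
        return val if np.isfinite(val) else 1e12


def _numerical_hessian(fun, x0, rel_step=1e-4):
    k = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# public fit


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a mixed model by marginal maximum likelihood.

    With no groupings and no dispersion covariate the fit reduces to OLS
    (identical coefficients); with groupings present each must have at least
    two observed levels.
    """
    data = data.reset_index(drop=True)
    if spec.response not in data.columns:
        raise InvalidInputError(f"response column {spec.response!r} not in data")
    y = data[spec.response].to_numpy(dtype=float)
    constant = None
    if spec.transform == "log-plus-constant":
        constant = spec.constant
        if constant is None:
            positive = y[y > 0]
            if positive.size == 0:
                raise InvalidInputError("log-plus-constant: no positive response values")
            constant = float(positive.min()) / 2.0
        if np.any(y + constant <= 0):
            raise InvalidInputError("log-plus-constant: y + constant not positive everywhere")
        y = np.log(y + constant)
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite response values")

    X, names = build_design(data, spec.fixed)
    Zs, qs = [], []
    for grouping in spec.groups:
        Z, q = _grouping_matrix(data, grouping)
        if q < 2:
            raise InvalidInputError(f"grouping {grouping} has fewer than 2 levels")
        Zs.append(Z)
        qs.append(q)
    disp_x = None
    if spec.dispersion is not None:
        disp_x = data[spec.dispersion].to_numpy(dtype=float)

    ml = _MarginalML(y, X, Zs, qs, disp_x)

    # start from the OLS residual variance split across components
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    mse = float(np.mean((y - X @ beta0) ** 2))
    mse = max(mse, 1e-10)
    k = len(qs)
    theta0 = np.empty(ml.n_theta())
    theta0[:k] = math.log(mse * 0.5 / max(k, 1)) if k else 0.0
    theta0[k] = math.log(mse * (0.5 if k else 1.0))
    if disp_x is not None:
        theta0[k + 1] = 0.0
    bounds = [( _LOGVAR_MIN, _LOGVAR_MAX)] * (k + 1)
    if disp_x is not None:
        bounds.append((-8.0, 8.0))

    res = sopt.minimize(ml.nll, theta0, method="L-BFGS-B", bounds=bounds,
                        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    if not res.success:
        res2 = sopt.minimize(ml.nll, res.x, method="Nelder-Mead",
                             options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-7})
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError("mixed-model likelihood did not converge", trace=res)
    theta = np.asarray(res.x, dtype=float)

    nll, beta, XtVX = ml.decompose(theta)
    if beta is None:
        raise ConvergenceError("variance parameters degenerate at optimum", trace=res)
    cov_beta = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    df_resid = max(ml.n - ml.p, 1)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)

    vc = {}
    for i, grouping in enumerate(spec.groups):
        name = ":".join(grouping)
        vc[name] = math.exp(theta[i])
        if theta[i] <= _LOGVAR_MIN + 1.0:
            warnings.warn(
                f"random-effect variance for {name} is numerically zero", SingularFitWarning
            )

    disp_names = ["(Intercept)"] + ([spec.dispersion] if disp_x is not None else [])
    disp_params = pd.Series(theta[k:], index=disp_names)

    # normal-approximation SEs for theta from the numerical Hessian
    disp_se = np.full(len(disp_names), np.nan)
    try:
        H = _numerical_hessian(ml.nll, theta)
        cov_theta = np.linalg.inv(H)
        d = np.diag(cov_theta)
        if np.all(d[k:] > 0):
            disp_se = np.sqrt(d[k:])
    except (np.linalg.LinAlgError, ValueError):
        pass

    n_theta = ml.n_theta()
    loglik = -nll
    aic = 2 * (ml.p + n_theta) - 2 * loglik
    fitted = X @ beta
    return FitResult(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        vc=vc,
        disp_params=disp_params,
        disp_bse=pd.Series(disp_se, index=disp_names),
        loglik=loglik,
        aic=aic,
        nobs=ml.n,
        df_resid=df_resid,
        fitted=fitted,
        residuals=y - fitted,
        converged=bool(res.success or np.isfinite(res.fun)),
        constant=constant,
        theta=theta,
        optimizer_message=str(res.message),
        _design_terms=spec.fixed,
    )


# ---------------------------------------------------------------------------
# the study's three hypothesis models

_PLOT_GROUPS = (("experiment", "composition"), ("experiment", "block"))


def h1_spec(dispersion: str | None = "richness") -> ModelSpec:
    """Stand productivity ~ richness + richness^2, nested intercepts, richness dispersion."""
    return ModelSpec(
        response="productivity",
        fixed=("richness", "richness^2"),
        groups=_PLOT_GROUPS,
        dispersion=dispersion,
    )


def fit_h1(data: pd.DataFrame, dispersion: str | None = "richness") -> FitResult:
    """Richness-productivity model: saturating effect via the quadratic term,
    with residual variance allowed to change with richness."""
    return fit_lmm(h1_spec(dispersion), data)


def fit_h3(data: pd.DataFrame, response: str, dispersion: str | None = "richness") -> FitResult:
    """Diversity-effect model: NBE/SE/CE ~ CWM_WD + CWM_LNC + FDis_WD + FDis_LNC."""
    if response not in {"nbe", "se", "ce"}:
        raise InvalidInputError("fit_h3 response must be one of 'nbe', 'se', 'ce'")
    spec = ModelSpec(
        response=response,
        fixed=("cwm_wd", "cwm_lnc", "fdis_wd", "fdis_lnc"),
        groups=_PLOT_GROUPS,
        dispersion=dispersion,
    )
    return fit_lmm(spec, data)


def fit_h4(
    data: pd.DataFrame,
    dispersion: str | None = "richness",
    constant: float | None = None,
) -> FitResult:
    """Species-level model: ln(species productivity + c) ~ richness x (WD, LNC),
    with an angiosperm/gymnosperm random intercept nested in experiment.

    c defaults to half the smallest positive species productivity in the
    analysis subset; the value used is recorded on the result.
    """
    spec = ModelSpec(
        response="productivity",
        fixed=("richness", "wd", "lnc", "richness:wd", "richness:lnc"),
        groups=_PLOT_GROUPS + (("experiment", "class"),),
        dispersion=dispersion,
        transform="log-plus-constant",
        constant=constant,
    )
    return fit_lmm(spec, data)


def coefficient_table(fit: FitResult) -> pd.DataFrame:
    """Tidy coefficient table (term, estimate, se, t, p) for CSV export."""
    out = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return out
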