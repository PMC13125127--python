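"""Panel spatial Durbin model and its specification battery.

The SDM for a balanced panel of n units over T periods,

    y_t = rho W y_t + alpha + X_t beta + W X_t theta + eps_t,

is estimated by concentrated maximum likelihood: the log-determinant
ln|I - rho W| is evaluated from the (precomputed) eigenvalues of W, the
likelihood is concentrated to a bounded scalar problem in rho, and the
slopes follow by least squares at the optimum. Fixed effects are removed by
within-demeaning before the spatial step; random effects use the Swamy-Arora
error-component quasi-demeaning estimated from the non-spatial within /
between regressions. Nested SAR (theta = 0) and SEM (spatial error) fits
support the LR / Wald specification tests; LM and robust LM statistics for
lag and error dependence follow Anselin-Bera-Florax, and the Hausman
statistic contrasts the fixed- and random-effects slope vectors.

Coefficient covariance comes from a central-difference Hessian of the full
log-likelihood (deterministic, no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import EstimationError, InvalidConfigError
from .weights import SpatialWeights

__all__ = [
    "SpatialDurbinRegressor", "SdmResult", "SpecTests",
    "fit_sdm", "vif", "lm_tests", "lr_wald_hausman", "robustness_suite",
]


# ---------------------------------------------------------------- panel utils

def panel_arrays(
    X: pd.DataFrame, y: pd.Series, w: SpatialWeights
) -> tuple[np.ndarray, np.ndarray, int, list]:
    """Stack a (unit, year)-indexed panel year-major in W's unit order."""
    years = sorted(y.index.get_level_values("year").unique())
    ys, Xs = [], []
    for yr in years:
        yt = y.xs(yr, level="year").reindex(w.ids)
        Xt = X.xs(yr, level="year").reindex(w.ids)
        if yt.isna().any() or Xt.isna().any().any():
            raise InvalidConfigError(f"unbalanced panel at year {yr}")
        ys.append(yt.to_numpy(dtype=float))
        Xs.append(Xt.to_numpy(dtype=float))
    return np.concatenate(ys), np.vstack(Xs), len(years), list(X.columns)


def _per_period(mat_w: np.ndarray, arr: np.ndarray, n: int, T: int) -> np.ndarray:
    """Apply W within each period of a year-major stacked array."""
    shaped = arr.reshape(T, n, -1)
    out = np.einsum("ij,tjk->tik", mat_w, shaped)
    return out.reshape(arr.shape)


def _within(arr: np.ndarray, n: int, T: int) -> np.ndarray:
    shaped = arr.reshape(T, n, -1)
    out = shaped - shaped.mean(axis=0, keepdims=True)
    return out.reshape(arr.shape)


def _unit_means(arr: np.ndarray, n: int, T: int) -> np.ndarray:
    return arr.reshape(T, n, -1).mean(axis=0).reshape(n, -1)


def _ols(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return coef, y - Z @ coef


def _re_theta(y: np.ndarray, X: np.ndarray, n: int, T: int) -> float:
    """Swamy-Arora quasi-demeaning factor from the non-spatial model."""
    k = X.shape[1]
    yw, Xw = _within(y[:, None], n, T).ravel(), _within(X, n, T)
    _, ew = _ols(yw, Xw)
    sigma_e2 = ew @ ew / max(n * (T - 1) - k, 1)
    ym = _unit_means(y[:, None], n, T).ravel()
    Xm = np.column_stack([np.ones(n), _unit_means(X, n, T)])
    _, eb = _ols(ym, Xm)
    sigma_12 = T * (eb @ eb) / max(n - Xm.shape[1], 1)
    sigma_12 = max(sigma_12, sigma_e2)  # variance components cannot be negative
    return 1.0 - np.sqrt(sigma_e2 / sigma_12)


def _log_jacobian(rho: float, eig: np.ndarray) -> float:
    vals = 1.0 - rho * eig
    if np.min(np.abs(vals)) < 1e-12:
        return -np.inf
    return float(np.sum(np.log(np.abs(vals))) if np.isrealobj(eig)
                 else np.real(np.sum(np.log(vals))))


# ------------------------------------------------------------------- results

@dataclass
class SdmResult:
    model: str
    effects: str
    rho: float
    params: pd.Series          # intercept?, betas, thetas, rho
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    llf: float
    r2: float
    n: int
    T: int
    cov: pd.DataFrame
    feature_names: list = field(default_factory=list)

    @property
    def beta(self) -> pd.Series:
        return self.params[[f for f in self.feature_names]]

    @property
    def theta(self) -> pd.Series:
        wx = [f"W_{f}" for f in self.feature_names]
        return self.params[[c for c in wx if c in self.params.index]]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "z": self.zvalues,
                             "p": self.pvalues})


# -------------------------------------------------------------- ML machinery

def _concentrated_fit(y, Wy, Z, eig, n, T, names, model, effects):
    """Concentrated ML over the spatial parameter; slopes by GLS step."""
    N = n * T
    d0, e0 = _ols(y, Z)
    d1, e1 = _ols(Wy, Z)
    lam_real = eig.real if np.iscomplexobj(eig) else eig
    lo = 1.0 / lam_real.min() + 1e-6 if lam_real.min() < 0 else -0.999999
    hi = 1.0 / lam_real.max() - 1e-6 if lam_real.max() > 0 else 0.999999

    def negll(rho):
        e = e0 - rho * e1
        s2 = (e @ e) / N
        if s2 <= 0:
            return np.inf
        return 0.5 * N * (np.log(2 * np.pi * s2) + 1) - T * _log_jacobian(rho, eig)

    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise EstimationError(f"spatial ML failed to converge: {res.message}")
    rho = float(res.x)
    if negll(0.0) < res.fun:  # the optimum can never beat the interior best
        rho = 0.0
    if min(rho - lo, hi - rho) < 1e-4:
        import warnings
        warnings.warn(f"spatial coefficient at interval boundary: {rho:.4f}",
                      stacklevel=3)
    delta = d0 - rho * d1
    e = e0 - rho * e1
    sigma2 = float(e @ e / N)
    llf = -float(negll(rho))
    fitted = rho * Wy + Z @ delta
    r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)

    # central-difference Hessian of the negative log-likelihood over
    # (delta, rho, ln sigma2); the log parametrization keeps the variance
    # positive at every finite step
    def nll_full(p):
        d, r, ls = p[:-2], p[-2], p[-1]
        s2 = np.exp(ls)
        resid = y - r * Wy - Z @ d
        return (0.5 * N * np.log(2 * np.pi * s2)
                + resid @ resid / (2 * s2)
                - T * _log_jacobian(r, eig))

    p0 = np.concatenate([delta, [rho, np.log(sigma2)]])
    H = _num_hessian(nll_full, p0)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    param_names = names + ["rho"]
    est = np.concatenate([delta, [rho]])
    cov = cov_full[:-1, :-1]
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zv = np.where(se > 0, est / se, np.nan)
    pv = 2 * stats.norm.sf(np.abs(zv))
    idx = pd.Index(param_names)
    features = [c for c in names if c not in ("const",) and not c.startswith("W_")]
    return SdmResult(
        model=model, effects=effects, rho=rho,
        params=pd.Series(est, index=idx), se=pd.Series(se, index=idx),
        zvalues=pd.Series(zv, index=idx), pvalues=pd.Series(pv, index=idx),
        sigma2=sigma2, llf=llf, r2=r2, n=n, T=T,
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        feature_names=features,
    )


def _num_hessian(fun, p0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    k = p0.size
    h = rel_step * np.maximum(np.abs(p0), 1e-3)
    H = np.empty((k, k))
    f0 = fun(p0)
    for i in range(k):
        for j in range(i, k):
            pi, pj = np.zeros(k), np.zeros(k)
            pi[i], pj[j] = h[i], h[j]
            if i == j:
                f1 = fun(p0 + pi)
                f2 = fun(p0 - pi)
                H[i, i] = (f1 - 2 * f0 + f2) / h[i] ** 2
            else:
                fpp = fun(p0 + pi + pj)
                fpm = fun(p0 + pi - pj)
                fmp = fun(p0 - pi + pj)
                fmm = fun(p0 - pi - pj)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _sem_fit(y, X_design, w, eig, n, T, names, effects):
    """Spatial-error ML: y = Z beta + u, u = lam W u + eps."""
    N = n * T
    Wy = _per_period(w.matrix, y[:, None], n, T).ravel()
    WZ = _per_period(w.matrix, X_design, n, T)
    lam_real = eig.real if np.iscomplexobj(eig) else eig
    lo = 1.0 / lam_real.min() + 1e-6 if lam_real.min() < 0 else -0.999999
    hi = 1.0 / lam_real.max() - 1e-6 if lam_real.max() > 0 else 0.999999

    def negll(lam):
        ys = y - lam * Wy
        Zs = X_design - lam * WZ
        _, e = _ols(ys, Zs)
        s2 = e @ e / N
        if s2 <= 0:
            return np.inf
        return 0.5 * N * (np.log(2 * np.pi * s2) + 1) - T * _log_jacobian(lam, eig)

    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(res.x)
    if negll(0.0) < res.fun:
        lam = 0.0
    ys = y - lam * Wy
    Zs = X_design - lam * WZ
    coef, e = _ols(ys, Zs)
    sigma2 = float(e @ e / N)
    llf = -float(negll(lam))
    idx = pd.Index(names + ["lambda"])
    est = np.concatenate([coef, [lam]])
    nanv = pd.Series(np.nan, index=idx)
    features = [c for c in names if c != "const"]
    return SdmResult(model="sem", effects=effects, rho=lam,
                     params=pd.Series(est, index=idx), se=nanv, zvalues=nanv,
                     pvalues=nanv, sigma2=sigma2, llf=llf,
                     r2=float(np.corrcoef(y, X_design @ coef)[0, 1] ** 2),
                     n=n, T=T, cov=pd.DataFrame(np.nan, index=idx, columns=idx),
                     feature_names=features)


# ------------------------------------------------------------ the estimator

class SpatialDurbinRegressor(BaseEstimator, RegressorMixin):
    """Panel spatial Durbin (or SAR / SEM) maximum-likelihood estimator.

    Parameters
    ----------
    weights : row-standardized SpatialWeights over the panel's units.
    effects : {"pooled", "fixed", "random"}. Fixed effects within-demean per
        unit; random effects quasi-demean with the Swamy-Arora factor
        estimated from the non-spatial model.
    model : {"sdm", "sar", "sem"}. "sar" drops the WX terms; "sem" moves the
        spatial process into the error.
    include_wx : legacy switch; include_wx=False is equivalent to model="sar".

    Attributes (after fit)
    ----------------------
    rho_, coef_ (betas), wx_coef_ (thetas), intercept_, sigma2_, llf_, r2_,
    result_ : full SdmResult with z and p per coefficient.
    """

    def __init__(self, weights: SpatialWeights | None = None,
                 effects: str = "random", model: str = "sdm",
                 include_wx: bool = True):
        self.weights = weights
        self.effects = effects
        self.model = model
        self.include_wx = include_wx

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "SpatialDurbinRegressor":
        w = self.weights
        if w is None:
            raise InvalidConfigError("SpatialDurbinRegressor requires weights")
        if not w.row_standardized:
            raise InvalidConfigError("W must be row-standardized for panel ML")
        if self.effects not in ("pooled", "fixed", "random"):
            raise InvalidConfigError(f"unknown effects {self.effects!r}")
        model = self.model if self.include_wx or self.model != "sdm" else "sar"
        yv, Xv, T, feat = panel_arrays(X, y, w)
        n = w.n
        if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
            raise EstimationError("regressor matrix is rank deficient")
        eig = np.linalg.eigvals(w.matrix)
        if np.allclose(eig.imag, 0):
            eig = eig.real
        WX = _per_period(w.matrix, Xv, n, T)
        Wy = _per_period(w.matrix, yv[:, None], n, T).ravel()

        if self.effects == "fixed":
            tf = lambda a: _within(a if a.ndim > 1 else a[:, None], n, T).reshape(a.shape)
            use_const = False
        elif self.effects == "random":
            th = _re_theta(yv, np.column_stack([Xv, WX]) if model == "sdm" else Xv,
                           n, T)
            self.re_theta_ = float(th)

            def tf(a):
                shaped = (a if a.ndim > 1 else a[:, None]).reshape(T, n, -1)
                out = shaped - th * shaped.mean(axis=0, keepdims=True)
                return out.reshape(a.shape)
            use_const = True
        else:
            tf = lambda a: a
            use_const = True

        yt, Wyt, Xt, WXt = tf(yv), tf(Wy), tf(Xv), tf(WX)
        names = []
        cols = []
        if use_const:
            const = tf(np.ones_like(yv)) if self.effects == "random" else np.ones_like(yv)
            cols.append(const[:, None] if const.ndim == 1 else const)
            names.append("const")
        cols.append(Xt)
        names += feat
        if model == "sdm":
            cols.append(WXt)
            names += [f"W_{f}" for f in feat]
        Z = np.column_stack(cols)

        if model in ("sdm", "sar"):
            self.result_ = _concentrated_fit(yt, Wyt, Z, eig, n, T, names,
                                             model, self.effects)
        elif model == "sem":
            self.result_ = _sem_fit(yt, Z, w, eig, n, T, names, self.effects)
        else:
            raise InvalidConfigError(f"unknown model {model!r}")
        res = self.result_
        self.rho_ = res.rho
        self.coef_ = res.beta.to_numpy() if model != "sem" else res.params[feat].to_numpy()
        self.wx_coef_ = (res.theta.to_numpy() if model == "sdm" else np.zeros(0))
        self.intercept_ = float(res.params.get("const", 0.0))
        self.sigma2_ = res.sigma2
        self.llf_ = res.llf
        self.r2_ = res.r2
        self.feature_names_in_ = np.array(feat, dtype=object)
        self.n_features_in_ = len(feat)
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Reduced-form prediction (I - rho W)^-1 (a + X b + WX t)."""
        w = self.weights
        years = sorted(X.index.get_level_values("year").unique())
        A_inv = np.linalg.inv(np.eye(w.n) - self.rho_ * w.matrix)
        out = []
        for yr in years:
            Xt = X.xs(yr, level="year").reindex(w.ids).to_numpy(dtype=float)
            mean = self.intercept_ + Xt @ self.coef_
            if self.wx_coef_.size:
                mean = mean + w.matrix @ Xt @ self.wx_coef_
            out.append(pd.Series(A_inv @ mean, index=pd.MultiIndex.from_product(
                [w.ids, [yr]], names=["unit", "year"])))
        return pd.concat(out).sort_index()


def fit_sdm(X, y, weights, effects="random", model="sdm") -> SdmResult:
    """Functional wrapper over SpatialDurbinRegressor."""
    est = SpatialDurbinRegressor(weights=weights, effects=effects, model=model)
    return est.fit(X, y).result_


# ------------------------------------------------------------ specification

@dataclass
class SpecTests:
    vif: pd.Series | None = None
    mean_vif: float | None = None
    lm_lag: float | None = None
    lm_lag_p: float | None = None
    robust_lm_lag: float | None = None
    robust_lm_lag_p: float | None = None
    lm_error: float | None = None
    lm_error_p: float | None = None
    robust_lm_error: float | None = None
    robust_lm_error_p: float | None = None
    lr_lag: float | None = None
    lr_lag_p: float | None = None
    lr_error: float | None = None
    lr_error_p: float | None = None
    wald_lag: float | None = None
    wald_lag_p: float | None = None
    wald_error: float | None = None
    wald_error_p: float | None = None
    hausman: float | None = None
    hausman_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.__dict__.items()
                if v is not None and not isinstance(v, pd.Series)]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def vif(X: pd.DataFrame) -> tuple[pd.Series, float]:
    """Variance inflation factors from auxiliary regressions (with constant)."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise InvalidConfigError("VIF needs at least two regressors")
    arr = np.asarray(X, dtype=float)
    out = {}
    for j, col in enumerate(cols):
        others = np.column_stack(
            [np.ones(arr.shape[0]), np.delete(arr, j, axis=1)])
        yj = arr[:, j]
        _, resid = _ols(yj, others)
        tss = ((yj - yj.mean()) ** 2).sum()
        rss = resid @ resid
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            raise EstimationError(f"perfect collinearity involving {col!r}")
        out[col] = 1.0 / (1.0 - r2)
    series = pd.Series(out)
    return series, float(series.mean())


def lm_tests(X: pd.DataFrame, y: pd.Series, weights: SpatialWeights) -> SpecTests:
    """Anselin-Bera-Florax LM and robust LM tests for spatial lag / error.

    Computed from pooled OLS (with intercept) residuals; W is applied within
    each period. Chi-square(1) p-values.
    """
    w = weights
    yv, Xv, T, _ = panel_arrays(X, y, w)
    n = w.n
    N = n * T
    Z = np.column_stack([np.ones(N), Xv])
    b, e = _ols(yv, Z)
    s2 = e @ e / N
    We = _per_period(w.matrix, e[:, None], n, T).ravel()
    Wy = _per_period(w.matrix, yv[:, None], n, T).ravel()
    t1 = T * float(np.trace(w.matrix.T @ w.matrix + w.matrix @ w.matrix))
    d_err = (e @ We) / s2
    d_lag = (e @ Wy) / s2
    WZb = _per_period(w.matrix, (Z @ b)[:, None], n, T).ravel()
    # projection off the regressors
    _, m_wzb = _ols(WZb, Z)
    J = (m_wzb @ m_wzb + t1 * s2) / s2
    lm_lag = d_lag ** 2 / J
    lm_err = d_err ** 2 / t1
    r_lag = (d_lag - d_err) ** 2 / (J - t1)
    r_err = (d_err - t1 / J * d_lag) ** 2 / (t1 * (1.0 - t1 / J))
    chi = stats.chi2(df=1)
    return SpecTests(
        lm_lag=float(lm_lag), lm_lag_p=float(chi.sf(lm_lag)),
        robust_lm_lag=float(r_lag), robust_lm_lag_p=float(chi.sf(r_lag)),
        lm_error=float(lm_err), lm_error_p=float(chi.sf(lm_err)),
        robust_lm_error=float(r_err), robust_lm_error_p=float(chi.sf(r_err)),
    )


def lr_wald_hausman(
    X: pd.DataFrame, y: pd.Series, weights: SpatialWeights,
    effects: str = "random",
) -> tuple[SpecTests, dict]:
    """LR (SDM vs SAR / SEM), Wald (theta = 0; common-factor) and Hausman.

    Returns the test battery and the dict of fitted models used to build it.
    """
    fits = {
        "sdm": fit_sdm(X, y, weights, effects=effects, model="sdm"),
        "sar": fit_sdm(X, y, weights, effects=effects, model="sar"),
        "sem": fit_sdm(X, y, weights, effects=effects, model="sem"),
    }
    k = len(fits["sdm"].feature_names)
    chi = stats.chi2(df=k)
    lr_lag = max(2.0 * (fits["sdm"].llf - fits["sar"].llf), 0.0)
    lr_err = max(2.0 * (fits["sdm"].llf - fits["sem"].llf), 0.0)

    sdm = fits["sdm"]
    theta_names = [f"W_{f}" for f in sdm.feature_names]
    th = sdm.params[theta_names].to_numpy()
    Vth = sdm.cov.loc[theta_names, theta_names].to_numpy()
    wald_lag = float(th @ np.linalg.solve(Vth, th))

    # common-factor restriction g = theta + rho * beta = 0 (delta method)
    beta_names = sdm.feature_names
    sel = beta_names + theta_names + ["rho"]
    V = sdm.cov.loc[sel, sel].to_numpy()
    beta = sdm.params[beta_names].to_numpy()
    rho = sdm.rho
    g = th + rho * beta
    G = np.zeros((k, 2 * k + 1))
    G[:, :k] = rho * np.eye(k)
    G[:, k:2 * k] = np.eye(k)
    G[:, -1] = beta
    Vg = G @ V @ G.T
    wald_err = float(g @ np.linalg.solve(Vg, g))

    fe = fit_sdm(X, y, weights, effects="fixed", model="sdm")
    re = fit_sdm(X, y, weights, effects="random", model="sdm")
    common = beta_names + theta_names
    d = (fe.params[common] - re.params[common]).to_numpy()
    Vd = (fe.cov.loc[common, common] - re.cov.loc[common, common]).to_numpy()
    hstat = float(d @ np.linalg.pinv(Vd) @ d)
    hstat = max(hstat, 0.0)  # finite-sample Vd need not be positive definite
    chi_h = stats.chi2(df=len(common))

    tests = SpecTests(
        lr_lag=lr_lag, lr_lag_p=float(chi.sf(lr_lag)),
        lr_error=lr_err, lr_error_p=float(chi.sf(lr_err)),
        wald_lag=wald_lag, wald_lag_p=float(chi.sf(wald_lag)),
        wald_error=wald_err, wald_error_p=float(chi.sf(wald_err)),
        hausman=hstat, hausman_p=float(chi_h.sf(hstat)),
    )
    return tests, fits


def robustness_suite(
    X: pd.DataFrame,
    y: pd.Series,
    weights: SpatialWeights,
    y_alternative: pd.Series | None = None,
    exclude: list | None = None,
    effects: str = "random",
) -> dict:
    """Baseline SDM plus robustness re-fits.

    Variants: (a) an alternative outcome (e.g. the entropy-weighted CCD),
    (b) a subsample excluding flagged units, with W rebuilt (subset +
    re-standardized) on the remaining units. Reports coefficient-sign
    agreement of each variant with the baseline.
    """
    out = {"baseline": fit_sdm(X, y, weights, effects=effects)}
    if y_alternative is not None:
        out["alternative_outcome"] = fit_sdm(X, y_alternative, weights,
                                             effects=effects)
    if exclude:
        keep = [u for u in weights.ids if u not in set(exclude)]
        if len(keep) <= X.shape[1] + 2:
            raise EstimationError("subset smaller than the regressor count")
        w_sub = weights.subset(keep)
        mask_x = X.index.get_level_values("unit").isin(keep)
        mask_y = y.index.get_level_values("unit").isin(keep)
        out["subset"] = fit_sdm(X[mask_x], y[mask_y], w_sub, effects=effects)
    base_sign = np.sign(out["baseline"].params)
    out["sign_agreement"] = {
        name: float((np.sign(res.params.reindex(base_sign.index)) ==
                     base_sign).mean())
        for name, res in out.items() if isinstance(res, SdmResult)
    }
    return out
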