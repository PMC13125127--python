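"""Hansen-style panel threshold regression with bootstrap inference.

A fixed-effects regression whose slope on a focal regressor switches when a
threshold variable q crosses an estimated threshold gamma:

    y_it = mu_i + x_it' delta + b1 q_it 1(q_it <= gamma)
                + b2 q_it 1(q_it > gamma) + eps_it.

All variables are within-demeaned per unit; gamma is chosen to minimize the
residual sum of squares over the observed values of q inside a trimmed
support. The existence of a threshold is tested with

    F = (RSS_linear - RSS_threshold) / MSE_threshold,  MSE = RSS / (n (T-1)),

whose nonstandard null distribution is approximated by a residual bootstrap
under the no-threshold model, re-estimating gamma in every replicate. A
second threshold is searched conditional on the first (with refinement of
the first), tested the same way against the single-threshold null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import EstimationError, InvalidConfigError

__all__ = ["PanelThresholdRegressor", "ThresholdFit", "fit_threshold",
           "bootstrap_f_test", "sequential_thresholds"]


@dataclass
class ThresholdFit:
    gammas: list
    rss: float
    mse: float
    rss_linear: float
    f_stat: float | None = None
    bootstrap_p: float | None = None
    critical_values: dict | None = None   # {0.10: ..., 0.05: ..., 0.01: ...}
    regime_coefs: pd.DataFrame | None = None
    trim: float = 0.05
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def gamma(self) -> float:
        return self.gammas[0]


def _within_by_unit(arr: np.ndarray, unit_codes: np.ndarray, n_units: int):
    """Demean each column within unit groups (unbalanced-safe)."""
    arr2 = arr if arr.ndim > 1 else arr[:, None]
    counts = np.bincount(unit_codes, minlength=n_units).astype(float)
    out = np.empty_like(arr2, dtype=float)
    for j in range(arr2.shape[1]):
        sums = np.bincount(unit_codes, weights=arr2[:, j], minlength=n_units)
        out[:, j] = arr2[:, j] - (sums / counts)[unit_codes]
    return out if arr.ndim > 1 else out[:, 0]


class _Panel:
    """Pre-demeaned panel pieces shared by the grid search and bootstrap."""

    def __init__(self, y, q, controls, units):
        self.units = np.asarray(units)
        uniq, codes = np.unique(self.units, return_inverse=True)
        self.codes = codes
        self.n_units = uniq.size
        self.y = np.asarray(y, dtype=float)
        self.q = np.asarray(q, dtype=float)
        self.controls = (np.asarray(controls, dtype=float)
                         if controls is not None else np.empty((self.y.size, 0)))
        self.N = self.y.size
        self.T_bar = self.N / self.n_units
        self.yd = _within_by_unit(self.y, codes, self.n_units)
        self.cd = (_within_by_unit(self.controls, codes, self.n_units)
                   if self.controls.shape[1] else self.controls)

    def dof(self, k_extra: int) -> int:
        # published MSE convention: within degrees of freedom n (T - 1)
        return self.N - self.n_units

    def design(self, gammas, yd=None):
        """Within-demeaned design with regime-split slopes on q."""
        gs = sorted(gammas)
        cols = []
        edges = [-np.inf] + list(gs) + [np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            cols.append(self.q * ((self.q > lo) & (self.q <= hi)))
        regime = _within_by_unit(np.column_stack(cols), self.codes, self.n_units)
        Z = np.column_stack([regime, self.cd]) if self.cd.shape[1] else regime
        return Z

    def rss(self, gammas, yd=None) -> float:
        yd = self.yd if yd is None else yd
        Z = self.design(gammas)
        coef, *_ = np.linalg.lstsq(Z, yd, rcond=None)
        e = yd - Z @ coef
        return float(e @ e)

    def linear_fit(self, yd=None):
        yd = self.yd if yd is None else yd
        qd = _within_by_unit(self.q, self.codes, self.n_units)
        Z = (np.column_stack([qd, self.cd]) if self.cd.shape[1] else qd[:, None])
        coef, *_ = np.linalg.lstsq(Z, yd, rcond=None)
        e = yd - Z @ coef
        return float(e @ e), Z @ coef, e


def _candidates(q: np.ndarray, trim: float, max_candidates: int | None):
    lo, hi = np.quantile(q, [trim, 1.0 - trim])
    cand = np.unique(q[(q >= lo) & (q <= hi)])
    if cand.size == 0:
        raise EstimationError("no candidate thresholds after trimming")
    if max_candidates is not None and cand.size > max_candidates:
        cand = np.unique(np.quantile(cand, np.linspace(0, 1, max_candidates)))
    return cand


class PanelThresholdRegressor(BaseEstimator):
    """Fixed-effects panel threshold regression (single or double threshold).

    Parameters
    ----------
    trim : fraction of the threshold variable's support trimmed per tail
        before the grid search (default 5%).
    max_candidates : optional cap on the candidate grid (quantile-thinned);
        None searches every observed value in the trimmed support.
    max_thresholds : 1 or 2 thresholds.
    n_bootstrap : residual-bootstrap replicates for the F tests.
    random_state : seed; the bootstrap is fully reproducible.

    Attributes (after fit)
    ----------------------
    gamma_ : estimated threshold(s), list
    single_ , double_ : ThresholdFit records (double_ only if requested)
    f_stat_, bootstrap_p_ : threshold-existence test of the selected model
    regime_coefs_ : slopes per regime with standard errors and 95% CIs
    """

    def __init__(self, trim: float = 0.05, max_candidates: int | None = None,
                 max_thresholds: int = 1, n_bootstrap: int = 300,
                 random_state: int | None = 0):
        self.trim = trim
        self.max_candidates = max_candidates
        self.max_thresholds = max_thresholds
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # -------------------------------------------------------------- fitting
    def fit(self, X: pd.DataFrame | None, y: pd.Series, *, q: pd.Series,
            units=None) -> "PanelThresholdRegressor":
        """``X`` holds the controls (may be None/empty); ``q`` the threshold
        variable (also the regime regressor); ``units`` the unit labels
        (defaults to the 'unit' level of y's index)."""
        if units is None:
            units = y.index.get_level_values("unit")
        qv = np.asarray(q, dtype=float)
        if np.unique(qv).size < 3:
            raise InvalidConfigError("threshold variable has too little variation")
        panel = _Panel(y, qv, X, units)
        per_unit = pd.Series(qv).groupby(np.asarray(units)).nunique()
        if (per_unit <= 1).all():
            raise InvalidConfigError("threshold variable must vary within units")
        cand = _candidates(panel.q, self.trim, self.max_candidates)
        if 0 < self.n_bootstrap < 50:
            import warnings
            warnings.warn(f"n_bootstrap={self.n_bootstrap} < 50: bootstrap "
                          "p-values will be coarse", stacklevel=2)

        rss_lin, fitted_lin, resid_lin = panel.linear_fit()
        rss_grid = np.array([panel.rss([g]) for g in cand])
        best = int(np.argmin(rss_grid))
        g1 = float(cand[best])
        rss1 = float(rss_grid[best])
        mse1 = rss1 / panel.dof(2)
        f1 = (rss_lin - rss1) / mse1
        rng = np.random.default_rng(self.random_state)
        p1, crit1 = self._bootstrap(panel, cand, rng, n_gammas_null=0,
                                    null_fitted=fitted_lin, null_resid=resid_lin,
                                    f_obs=f1)
        self.single_ = ThresholdFit(
            gammas=[g1], rss=rss1, mse=mse1, rss_linear=rss_lin,
            f_stat=float(f1), bootstrap_p=p1, critical_values=crit1,
            regime_coefs=self._coefs(panel, [g1]),
            trim=self.trim, n_bootstrap=self.n_bootstrap, seed=self.random_state)
        self.double_ = None

        if self.max_thresholds >= 2:
            self.double_ = self._fit_double(panel, cand, g1, rss1, rng)

        chosen = (self.double_ if self.double_ is not None
                  and (self.double_.bootstrap_p or 1) < 0.05 else self.single_)
        self.gamma_ = chosen.gammas
        self.f_stat_ = chosen.f_stat
        self.bootstrap_p_ = chosen.bootstrap_p
        self.regime_coefs_ = chosen.regime_coefs
        self.fit_ = chosen
        return self

    def _fit_double(self, panel, cand, g1, rss1, rng):
        others = cand[cand != g1]
        if others.size == 0:
            return None
        rss2_grid = np.array([panel.rss(sorted([g1, g])) for g in others])
        b = int(np.argmin(rss2_grid))
        g2 = float(others[b])
        # refinement: re-search the first threshold holding the second fixed
        refine = cand[cand != g2]
        rss_ref = np.array([panel.rss(sorted([g, g2])) for g in refine])
        rb = int(np.argmin(rss_ref))
        g1r = float(refine[rb])
        gammas = sorted([g1r, g2])
        rss2 = float(rss_ref[rb])
        mse2 = rss2 / panel.dof(3)
        f2 = (rss1 - rss2) / mse2
        # bootstrap under the single-threshold null
        Z1 = panel.design([g1])
        coef1, *_ = np.linalg.lstsq(Z1, panel.yd, rcond=None)
        fitted1 = Z1 @ coef1
        resid1 = panel.yd - fitted1
        p2, crit2 = self._bootstrap(panel, cand, rng, n_gammas_null=1,
                                    null_fitted=fitted1, null_resid=resid1,
                                    f_obs=f2)
        return ThresholdFit(
            gammas=gammas, rss=rss2, mse=mse2, rss_linear=rss1,
            f_stat=float(f2), bootstrap_p=p2, critical_values=crit2,
            regime_coefs=self._coefs(panel, gammas),
            trim=self.trim, n_bootstrap=self.n_bootstrap, seed=self.random_state)

    def _bootstrap(self, panel, cand, rng, n_gammas_null, null_fitted,
                   null_resid, f_obs):
        if self.n_bootstrap <= 0:
            return None, None
        fs = np.empty(self.n_bootstrap)
        for b in range(self.n_bootstrap):
            eb = rng.choice(null_resid, size=panel.N, replace=True)
            # treat the bootstrap sample as raw data: re-apply the within
            # transformation so the fixed effects are swept out again
            yb = _within_by_unit(null_fitted + eb, panel.codes, panel.n_units)
            if n_gammas_null == 0:
                qd = _within_by_unit(panel.q, panel.codes, panel.n_units)
                Z0 = (np.column_stack([qd, panel.cd]) if panel.cd.shape[1]
                      else qd[:, None])
                c0, *_ = np.linalg.lstsq(Z0, yb, rcond=None)
                rss0 = float(np.sum((yb - Z0 @ c0) ** 2))
                rss_b = np.array([panel.rss([g], yd=yb) for g in cand])
                rss_alt = rss_b.min()
                dof = panel.dof(2)
            else:
                rss_b1 = np.array([panel.rss([g], yd=yb) for g in cand])
                i1 = int(np.argmin(rss_b1))
                rss0 = float(rss_b1[i1])
                gb1 = cand[i1]
                oth = cand[cand != gb1]
                rss_b2 = np.array([panel.rss(sorted([gb1, g]), yd=yb)
                                   for g in oth])
                rss_alt = float(rss_b2.min())
                dof = panel.dof(3)
            fs[b] = (rss0 - rss_alt) / (rss_alt / dof)
        p = float((fs >= f_obs).mean())
        crit = {0.10: float(np.quantile(fs, 0.90)),
                0.05: float(np.quantile(fs, 0.95)),
                0.01: float(np.quantile(fs, 0.99))}
        return p, crit

    def _coefs(self, panel, gammas) -> pd.DataFrame:
        Z = panel.design(gammas)
        coef, *_ = np.linalg.lstsq(Z, panel.yd, rcond=None)
        e = panel.yd - Z @ coef
        dof = panel.dof(len(gammas) + 1) - Z.shape[1]
        s2 = e @ e / dof
        cov = s2 * np.linalg.pinv(Z.T @ Z)
        se = np.sqrt(np.diag(cov))
        tvals = np.where(se > 0, coef / se, np.nan)
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
        tcrit = stats.t.ppf(0.975, dof)
        gs = sorted(gammas)
        names = []
        edges = ["-inf"] + [f"{g:g}" for g in gs]
        for lo, hi in zip(edges, [f"{g:g}" for g in gs] + ["inf"]):
            names.append(f"q({lo},{hi}]")
        if panel.controls.shape[1]:
            names += [f"ctrl_{j}" for j in range(panel.controls.shape[1])]
        return pd.DataFrame({
            "coef": coef, "se": se, "t": tvals, "p": pvals,
            "ci_lo": coef - tcrit * se, "ci_hi": coef + tcrit * se,
        }, index=names)


def fit_threshold(y, q, controls=None, trim=0.05, max_candidates=None,
                  n_bootstrap=0, random_state=0) -> ThresholdFit:
    """Point estimation of a single threshold (functional wrapper)."""
    est = PanelThresholdRegressor(trim=trim, max_candidates=max_candidates,
                                  n_bootstrap=n_bootstrap,
                                  random_state=random_state)
    est.fit(controls, y, q=q)
    return est.single_


def bootstrap_f_test(y, q, controls=None, trim=0.05, max_candidates=None,
                     n_bootstrap=300, random_state=0) -> ThresholdFit:
    """Single-threshold fit plus the bootstrap F test of its existence."""
    est = PanelThresholdRegressor(trim=trim, max_candidates=max_candidates,
                                  n_bootstrap=n_bootstrap,
                                  random_state=random_state)
    est.fit(controls, y, q=q)
    return est.single_


def sequential_thresholds(y, q, controls=None, trim=0.05, max_candidates=None,
                          n_bootstrap=300, random_state=0):
    """Single and double threshold fits with sequential bootstrap tests."""
    est = PanelThresholdRegressor(trim=trim, max_candidates=max_candidates,
                                  max_thresholds=2, n_bootstrap=n_bootstrap,
                                  random_state=random_state)
    est.fit(controls, y, q=q)
    return est.single_, est.double_
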