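"""Regression and testing toolkit for g_m-trait relationships.

Pairwise g_m-trait relationships are characterised with robust M-estimation
regressions (Tukey bisquare, tuning constant 4.685): linear fits for traits
with linear structure and power-law fits y = a x^b where the relationship is
curvilinear (e.g. the Fick's-law drawdown, which is inversely proportional to
g_m at a given A_n).  Significance is only reported when the number of
measurements is at least 12 (configurable gate).

Because g_m is right-skewed (approximately gamma rather than normal), its
mean response to anatomical covariates is modelled with a gamma GLM with a
log link,

    log E[g_m,25] = b0 + b1 * Sc + b2 * Tcw,

whose coefficients are reported on the exp scale: one unit of S_c (or T_cw)
multiplies the expected g_m,25 by exp(b1) (or exp(b2)).  Fit quality is
McFadden's pseudo-R^2 = 1 - lnL(full)/lnL(null) against an intercept-only
gamma GLM.  Group medians are compared with Dunn's rank-based test with tie
correction and Holm adjustment.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

__all__ = [
    "TUKEY_C",
    "REPORTING_MIN_N",
    "RegressionResult",
    "GlmFit",
    "RobustLinearRegression",
    "RobustPowerRegression",
    "GammaGLMRegressor",
    "robust_linear_fit",
    "robust_power_fit",
    "fit_gamma_glm",
    "mcfadden_r2",
    "dunn_test",
    "gate_significance",
]

TUKEY_C = 4.685        # bisquare tuning constant (95% Gaussian efficiency)
REPORTING_MIN_N = 12   # significance reported only when n >= 12


@dataclass
class RegressionResult:
    """A pairwise regression outcome.

    ``coefficients`` is (intercept, slope) for linear fits and
    (amplitude, exponent) for power fits; ``reported`` applies the n >= 12
    significance-reporting gate.
    """

    form: str
    coefficients: tuple[float, float]
    r2: float
    pvalue: float
    n: int
    reported: bool


@dataclass
class GlmFit:
    """Gamma GLM of g_m,25 on S_c and T_cw, on the exp(beta) scale."""

    exp_beta0: float
    exp_beta1: float
    exp_beta2: float
    ci: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    pseudo_r2: float
    n_measurements: int
    n_studies: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, value in (
            ("exp_beta0", self.exp_beta0),
            ("exp_beta1", self.exp_beta1),
            ("exp_beta2", self.exp_beta2),
        ):
            lo, hi = self.ci[name]
            rows.append(
                {
                    "coefficient": name,
                    "estimate": value,
                    "ci_low": lo,
                    "ci_high": hi,
                    "pvalue": self.pvalues[name],
                }
            )
        out = pd.DataFrame(rows)
        out["pseudo_r2"] = self.pseudo_r2
        out["n_measurements"] = self.n_measurements
        out["n_studies"] = self.n_studies
        return out


def _weighted_r2(y, fitted, w) -> float:
    """Robust weighted R^2: 1 - sum(w r^2) / sum(w (y - ybar_w)^2)."""
    resid = y - fitted
    ybar = np.sum(w * y) / np.sum(w)
    denom = float(np.sum(w * (y - ybar) ** 2))
    if denom == 0:
        return np.nan
    return 1.0 - float(np.sum(w * resid**2)) / denom


class RobustLinearRegression(BaseEstimator, RegressorMixin):
    """Robust simple linear regression by Tukey-bisquare M-estimation.

    IRLS (statsmodels RLM) with tuning constant 4.685, to relative tolerance
    1e-8 or 50 iterations.  ``r2_`` is the robust weighted R^2 and
    ``pvalue_`` comes from the slope's robust standard error.
    """

    def __init__(self, tuning: float = TUKEY_C, max_iter: int = 50,
                 tol: float = 1e-8, min_n: int = REPORTING_MIN_N):
        self.tuning = tuning
        self.max_iter = max_iter
        self.tol = tol
        self.min_n = min_n

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        x = x[:, 0] if x.ndim == 2 else x
        y = np.asarray(y, dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        x, y = x[finite], y[finite]
        if len(x) < 3:
            raise ValueError(f"need at least 3 finite pairs, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("x is constant: slope is unidentifiable")
        exog = sm.add_constant(x)
        model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=self.tuning))
        with warnings.catch_warnings():
            # zero residual scale (exact fit) is a legitimate limiting case
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = model.fit(maxiter=self.max_iter, tol=self.tol, conv="coefs")
        self.intercept_ = float(res.params[0])
        self.coef_ = np.array([res.params[1]])
        try:
            self.weights_ = np.asarray(res.weights, dtype=float)
        except AttributeError:  # perfect fit: IRLS stopped before weighting
            self.weights_ = np.ones_like(y)
        self.r2_ = _weighted_r2(y, res.fittedvalues, self.weights_)
        self.pvalue_ = float(res.pvalues[1])
        self.n_ = len(x)
        self.reported_ = self.n_ >= self.min_n
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float)
        x = x[:, 0] if x.ndim == 2 else x
        return self.intercept_ + self.coef_[0] * x

    def result(self) -> RegressionResult:
        check_is_fitted(self, "coef_")
        return RegressionResult(
            form="linear",
            coefficients=(self.intercept_, float(self.coef_[0])),
            r2=self.r2_, pvalue=self.pvalue_, n=self.n_, reported=self.reported_,
        )


class RobustPowerRegression(BaseEstimator, RegressorMixin):
    """Robust power-law fit y = a x^b on the original scale.

    Start values come from a robust linear fit of log y on log x; the fit
    then iterates reweighted nonlinear least squares with Tukey-bisquare
    weights (same tuning, tolerance and iteration cap as the linear
    machinery) so gross outliers are downweighted on the scale of y, not of
    log y.  Requires x > 0 and y > 0.
    """

    def __init__(self, tuning: float = TUKEY_C, max_iter: int = 50,
                 tol: float = 1e-8, min_n: int = REPORTING_MIN_N):
        self.tuning = tuning
        self.max_iter = max_iter
        self.tol = tol
        self.min_n = min_n

    @staticmethod
    def _model(params, x):
        a, b = params
        return a * np.power(x, b)

    def _weights(self, resid):
        scale = stats.median_abs_deviation(resid, scale="normal")
        if scale <= 0 or not np.isfinite(scale):
            return np.ones_like(resid), 0.0
        u = resid / (self.tuning * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        return w, scale

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        x = x[:, 0] if x.ndim == 2 else x
        y = np.asarray(y, dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        x, y = x[finite], y[finite]
        if len(x) < 5:
            raise ValueError(f"need at least 5 finite pairs, got {len(x)}")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power-law fit requires x > 0 and y > 0")

        lin = RobustLinearRegression(tuning=self.tuning).fit(np.log(x), np.log(y))
        params = np.array([np.exp(lin.intercept_), lin.coef_[0]], dtype=float)
        w = np.ones_like(y)
        for _ in range(self.max_iter):
            resid = y - self._model(params, x)
            w, scale = self._weights(resid)
            if scale == 0.0:  # exact fit: residual scale collapsed
                break
            if np.sum(w > 0) < 3:
                raise RuntimeError(
                    "robust power fit diverged: fewer than 3 points with "
                    f"non-zero weight (params={params.tolist()})"
                )
            sw = np.sqrt(w)
            sol = optimize.least_squares(
                lambda p: sw * (y - self._model(p, x)), params, method="lm",
                max_nfev=5000,
            )
            if not sol.success:
                raise RuntimeError(f"inner least-squares failed: {sol.message}")
            step = np.max(np.abs(sol.x - params) / np.maximum(np.abs(params), 1e-12))
            params = sol.x
            if step < self.tol:
                break

        self.amplitude_, self.exponent_ = float(params[0]), float(params[1])
        self.weights_ = w
        fitted = self._model(params, x)
        self.r2_ = _weighted_r2(y, fitted, w)
        self.pvalue_ = self._exponent_pvalue(x, y, params, w)
        self.n_ = len(x)
        self.reported_ = self.n_ >= self.min_n
        return self

    def _exponent_pvalue(self, x, y, params, w) -> float:
        # Wald test from the weighted Gauss-Newton covariance at the solution.
        a, b = params
        resid = y - self._model(params, x)
        J = np.column_stack([np.power(x, b), a * np.power(x, b) * np.log(x)])
        Jw = J * w[:, None]
        dof = max(np.sum(w) - 2.0, 1.0)
        s2 = float(np.sum(w * resid**2)) / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ Jw)
        except np.linalg.LinAlgError:
            return np.nan
        se_b = np.sqrt(max(cov[1, 1], 0.0))
        if se_b == 0:
            return 0.0
        t = b / se_b
        return float(2.0 * stats.t.sf(np.abs(t), df=dof))

    def predict(self, X):
        check_is_fitted(self, "amplitude_")
        x = np.asarray(X, dtype=float)
        x = x[:, 0] if x.ndim == 2 else x
        return self._model((self.amplitude_, self.exponent_), x)

    def result(self) -> RegressionResult:
        check_is_fitted(self, "amplitude_")
        return RegressionResult(
            form="power",
            coefficients=(self.amplitude_, self.exponent_),
            r2=self.r2_, pvalue=self.pvalue_, n=self.n_, reported=self.reported_,
        )


class GammaGLMRegressor(BaseEstimator, RegressorMixin):
    """Gamma GLM with log link: log E[y] = b0 + X @ beta.

    Dispersion by the Pearson chi-square estimate; Wald 95% confidence
    intervals on the link scale, exponentiated for reporting.  The pseudo-R^2
    is McFadden's, against an intercept-only gamma GLM refitted on the same
    rows.
    """

    def __init__(self, min_n: int = 10):
        self.min_n = min_n

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        finite = np.isfinite(y) & np.all(np.isfinite(Xa), axis=1)
        Xa, y = Xa[finite], y[finite]
        if len(y) < self.min_n:
            raise ValueError(f"need at least {self.min_n} complete cases, got {len(y)}")
        if np.any(y <= 0):
            raise ValueError("gamma GLM requires a strictly positive response")
        for j, name in enumerate(names):
            if np.ptp(Xa[:, j]) == 0:
                raise ValueError(f"covariate {name!r} is constant: unidentifiable")

        exog = sm.add_constant(Xa)
        family = sm.families.Gamma(link=sm.families.links.Log())
        with warnings.catch_warnings():
            # the zero-dispersion limit (exact mean structure) is legitimate
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = sm.GLM(y, exog, family=family).fit()  # Pearson-chi2 scale
            null = sm.GLM(y, np.ones((len(y), 1)), family=family).fit()

        self.feature_names_ = names
        self.params_ = np.asarray(res.params, dtype=float)
        self.exp_params_ = np.exp(self.params_)
        ci = np.exp(res.conf_int())
        self.conf_int_exp_ = np.asarray(ci, dtype=float)
        self.pvalues_ = np.asarray(res.pvalues, dtype=float)
        self.scale_ = float(res.scale)
        self.llf_ = float(res.llf)
        self.llf_null_ = float(null.llf)
        self.pseudo_r2_ = mcfadden_r2(self.llf_, self.llf_null_)
        self.n_ = len(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        return np.exp(sm.add_constant(Xa, has_constant="add") @ self.params_)


def robust_linear_fit(x, y, min_n: int = REPORTING_MIN_N) -> RegressionResult:
    """Robust linear regression of y on x (thin wrapper)."""
    return RobustLinearRegression(min_n=min_n).fit(x, y).result()


def robust_power_fit(x, y, min_n: int = REPORTING_MIN_N) -> RegressionResult:
    """Robust power-law regression y = a x^b (thin wrapper)."""
    return RobustPowerRegression(min_n=min_n).fit(x, y).result()


def fit_gamma_glm(gm_25, Sc, Tcw, study_id=None) -> GlmFit:
    """Gamma log-link GLM of g_m,25 on S_c and T_cw, exp-scale report.

    Complete cases on (g_m,25, S_c, T_cw); ``study_id`` (optional, aligned)
    only feeds the distinct-study count in the report.
    """
    df = pd.DataFrame({
        "gm_25": np.asarray(gm_25, dtype=float),
        "Sc": np.asarray(Sc, dtype=float),
        "Tcw": np.asarray(Tcw, dtype=float),
    })
    if study_id is not None:
        df["study_id"] = np.asarray(study_id)
    complete = df[["gm_25", "Sc", "Tcw"]].notna().all(axis=1)
    df = df.loc[complete]
    est = GammaGLMRegressor().fit(df[["Sc", "Tcw"]], df["gm_25"].to_numpy())
    names = ("exp_beta0", "exp_beta1", "exp_beta2")
    return GlmFit(
        exp_beta0=float(est.exp_params_[0]),
        exp_beta1=float(est.exp_params_[1]),
        exp_beta2=float(est.exp_params_[2]),
        ci={n: (float(lo), float(hi)) for n, (lo, hi) in zip(names, est.conf_int_exp_)},
        pvalues={n: float(p) for n, p in zip(names, est.pvalues_)},
        pseudo_r2=float(est.pseudo_r2_),
        n_measurements=int(est.n_),
        n_studies=int(df["study_id"].nunique()) if "study_id" in df else None,
    )


def mcfadden_r2(loglik_full: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2 = 1 - lnL(full)/lnL(null) for nested fits."""
    if loglik_null == 0:
        raise ValueError("null log-likelihood is zero: pseudo-R2 undefined")
    return 1.0 - loglik_full / loglik_null


def dunn_test(
    values,
    groups,
    p_adjust: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's test of multiple comparisons between group medians.

    Rank-based pairwise z statistics with tie correction on the pooled ranks;
    p-values are two-sided normal and adjusted with ``p_adjust`` (any method
    statsmodels ``multipletests`` accepts; ``none`` disables).  Groups whose
    values are all missing are dropped with a warning.

    Returns one row per pair: group1, group2, z, pvalue, pvalue_adjusted,
    significant (at ``alpha``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]

    labels = [g for g in pd.unique(groups)]
    sizes = {g: int(np.sum(groups == g)) for g in labels}
    empty = [g for g, n in sizes.items() if n == 0]
    for g in empty:  # pragma: no cover - only reachable via all-NaN groups
        warnings.warn(f"group {g!r} has no finite values; dropped", stacklevel=2)
        labels.remove(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if any(sizes[g] < 2 for g in labels):
        raise ValueError("each group needs at least 2 values")

    N = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(np.mean(ranks[groups == g])) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))

    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        if var <= 0:
            z = 0.0
        else:
            z = (mean_rank[g1] - mean_rank[g2]) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "pvalue": p})
    out = pd.DataFrame(rows)
    if p_adjust and p_adjust.lower() != "none":
        out["pvalue_adjusted"] = multipletests(out["pvalue"], method=p_adjust)[1]
    else:
        out["pvalue_adjusted"] = out["pvalue"]
    out["significant"] = out["pvalue_adjusted"] < alpha
    return out


def gate_significance(
    result: RegressionResult, min_n: int = REPORTING_MIN_N
) -> RegressionResult:
    """Apply the minimum-sample reporting gate: reported iff n >= min_n."""
    return dataclasses.replace(result, reported=result.n >= min_n)
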