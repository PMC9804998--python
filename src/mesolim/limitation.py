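"""Photosynthetic limitation by mesophyll conductance.

The relative limitation L_m = (A_np - A_n)/A_np * 100 (%) quantifies by how
much net photosynthesis could be enhanced if g_m were infinitely high, where
A_np is net photosynthesis at C_c = C_i (infinite g_m, stomata as measured).
Across species, L_m declines approximately exponentially with g_m;
:class:`LimitationCurve` fits

    L_m = a * exp(-b * g_m)

by plain nonlinear least squares (a: amplitude in %, b: decay rate in
mol-1 m2 s, stored positive) with a seeded nonparametric bootstrap for the
95% confidence band.  Point exclusions (e.g. a manually excluded species)
are an explicit caller-supplied id list, never automatic.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "compute_Lm",
    "LimitationCurve",
    "LimitationFitError",
    "fit_limitation_curve",
    "predict_Lm",
    "pft_limitation_ranges",
]


class LimitationFitError(RuntimeError):
    """Nonlinear limitation-curve fit failed to converge."""


def compute_Lm(An, Anp):
    """Relative photosynthetic limitation by g_m, in percent.

    L_m = (A_np - A_n)/A_np * 100; scale-invariant in (A_n, A_np).  L_m lies
    in [0, 100) for 0 <= A_n <= A_np; A_n > A_np yields a negative L_m, which
    is returned (callers flag it).  Raises for A_np <= 0.
    """
    An = np.asarray(An, dtype=float)
    Anp = np.asarray(Anp, dtype=float)
    if np.any(Anp[np.isfinite(Anp)] <= 0):
        raise ValueError("Anp must be positive")
    Lm = (Anp - An) / Anp * 100.0
    return float(Lm) if Lm.ndim == 0 else Lm


def _exp_model(gm, a, b):
    return a * np.exp(-b * gm)


class LimitationCurve(BaseEstimator, RegressorMixin):
    """Exponential limitation curve L_m = a exp(-b g_m).

    Parameters
    ----------
    n_bootstrap : int
        Nonparametric bootstrap resamples for the confidence band (0 disables
        the band).
    ci_level : float
        Band coverage (default 0.95).
    random_state : int or None
        Seed for the bootstrap.
    n_restarts : int
        Extra perturbed restarts tried when the first optimisation fails.

    Attributes
    ----------
    amplitude_ : float
        a, the limitation at g_m -> 0 (%).
    decay_ : float
        b, stored positive (mol-1 m2 s).
    r2_ : float
        1 - SS_res/SS_tot of the nonlinear fit.
    bootstrap_params_ : ndarray of shape (n_bootstrap, 2)
        Bootstrap (a, b) draws backing the band; empty when disabled.
    n_ : int
        Number of pairs used (after exclusions).
    """

    def __init__(self, n_bootstrap: int = 1000, ci_level: float = 0.95,
                 random_state: int | None = None, n_restarts: int = 10):
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state
        self.n_restarts = n_restarts

    # -- fitting -------------------------------------------------------

    @staticmethod
    def _start_values(gm, lm):
        pos = lm > 0
        if pos.sum() >= 2 and np.ptp(gm[pos]) > 0:
            slope, intercept = np.polyfit(gm[pos], np.log(lm[pos]), 1)
            a0, b0 = float(np.exp(intercept)), float(-slope)
        else:
            a0, b0 = float(np.max(lm)), 1.0
        if not np.isfinite(a0) or a0 <= 0:
            a0 = max(float(np.max(lm)), 1.0)
        if not np.isfinite(b0) or b0 <= 0:
            b0 = 1.0
        return a0, b0

    def _fit_once(self, gm, lm, rng=None):
        a0, b0 = self._start_values(gm, lm)
        starts = [(a0, b0)]
        rng = rng or np.random.default_rng(0)
        starts += [
            (a0 * float(rng.uniform(0.3, 3.0)), b0 * float(rng.uniform(0.3, 3.0)))
            for _ in range(self.n_restarts)
        ]
        last_err = None
        for p0 in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _exp_model, gm, lm, p0=p0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
                    )
                return float(popt[0]), float(popt[1])
            except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
                last_err = err
        raise LimitationFitError(
            f"limitation-curve fit failed after {len(starts)} starts "
            f"(n={len(gm)}, gm range=({gm.min():.3g}, {gm.max():.3g})): {last_err}"
        )

    def fit(self, X, y, exclude: Sequence[int] | None = None):
        """Fit on pairs (g_m, L_m).

        ``X`` is g_m (1d or a single column), ``y`` is L_m in percent.
        ``exclude`` lists integer positions (or index labels for pandas
        inputs) dropped before fitting; they are recorded in
        ``excluded_points_``.
        """
        if isinstance(X, pd.Series):
            labels = X.index
            gm = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            gm = arr[:, 0] if arr.ndim == 2 else arr
            labels = pd.RangeIndex(len(gm))
        lm = np.asarray(y, dtype=float)
        if gm.shape != lm.shape:
            raise ValueError("X and y must have matching length")

        keep = np.ones(len(gm), dtype=bool)
        excluded = []
        if exclude is not None:
            positions = labels.get_indexer(list(exclude))
            if np.any(positions < 0):
                raise KeyError(f"exclude ids not found: {list(exclude)}")
            keep[positions] = False
            excluded = list(exclude)
        finite = np.isfinite(gm) & np.isfinite(lm)
        keep &= finite
        gm, lm = gm[keep], lm[keep]
        if np.any(gm <= 0):
            raise ValueError("gm must be positive")
        if len(gm) < 5:
            raise ValueError(f"need at least 5 pairs after exclusion, got {len(gm)}")

        rng = np.random.default_rng(self.random_state)
        a, b = self._fit_once(gm, lm, rng)
        resid = lm - _exp_model(gm, a, b)
        ss_tot = float(np.sum((lm - lm.mean()) ** 2))
        self.amplitude_, self.decay_ = a, b
        self.r2_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        self.n_ = len(gm)
        self.excluded_points_ = excluded

        boots = []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, len(gm), len(gm))
            try:
                boots.append(self._fit_once(gm[idx], lm[idx], rng))
            except LimitationFitError:  # pragma: no cover - degenerate resample
                continue
        self.bootstrap_params_ = np.asarray(boots, dtype=float).reshape(-1, 2)
        return self

    # -- prediction ----------------------------------------------------

    def predict(self, X):
        """Point prediction a exp(-b g_m), in percent."""
        check_is_fitted(self, "amplitude_")
        gm = np.asarray(X, dtype=float)
        gm = gm[:, 0] if gm.ndim == 2 else gm
        return _exp_model(gm, self.amplitude_, self.decay_)

    def predict_interval(self, X):
        """(lower, upper) percentile bootstrap band at ``ci_level``."""
        check_is_fitted(self, "amplitude_")
        if len(getattr(self, "bootstrap_params_", [])) == 0:
            raise ValueError("no bootstrap band available (n_bootstrap=0)")
        gm = np.asarray(X, dtype=float)
        gm = gm[:, 0] if gm.ndim == 2 else gm
        curves = _exp_model(
            gm[None, :], self.bootstrap_params_[:, :1], self.bootstrap_params_[:, 1:2]
        )
        alpha = (1.0 - self.ci_level) / 2.0
        lower = np.quantile(curves, alpha, axis=0)
        upper = np.quantile(curves, 1.0 - alpha, axis=0)
        return lower, upper

    def to_dict(self) -> dict:
        check_is_fitted(self, "amplitude_")
        return {
            "model": "Lm = a * exp(-b * gm)",
            "a_percent": self.amplitude_,
            "b_per_mol_m2_s": self.decay_,
            "r2": self.r2_,
            "n": self.n_,
            "n_bootstrap": int(len(self.bootstrap_params_)),
            "ci_level": self.ci_level,
            "excluded_points": list(self.excluded_points_),
        }


def fit_limitation_curve(
    gm, Lm, exclude: Sequence[int] | None = None, **kwargs
) -> LimitationCurve:
    """Fit :class:`LimitationCurve` on (g_m, L_m) pairs (thin wrapper)."""
    return LimitationCurve(**kwargs).fit(gm, Lm, exclude=exclude)


def predict_Lm(gm, fit) -> np.ndarray | float:
    """Evaluate a limitation curve at g_m.

    ``fit`` is a fitted :class:`LimitationCurve` or an ``(a, b)`` pair of
    curve coefficients (amplitude in %, positive decay rate).
    """
    gm_arr = np.asarray(gm, dtype=float)
    if np.any(gm_arr < 0):
        raise ValueError("gm must be non-negative")
    if isinstance(fit, LimitationCurve):
        out = fit.predict(np.atleast_1d(gm_arr))
    else:
        a, b = fit
        out = _exp_model(np.atleast_1d(gm_arr), a, b)
    return float(out[0]) if gm_arr.ndim == 0 else out


def pft_limitation_ranges(
    gm_25_by_pft: Mapping[str, Sequence[float]] | pd.DataFrame,
    fit: LimitationCurve,
    min_n: int = 4,
) -> pd.DataFrame:
    """Typical limitation range per PFT over the g_m,25 interquartile range.

    For each PFT with at least ``min_n`` values: low = lower confidence bound
    of the curve at the PFT's Q3 of g_m,25, high = upper bound at Q1 (the
    widest defensible combination of the band with the interquartile range);
    reported rounded to integer percent.  Without a bootstrap band, point
    predictions are used with a warning.
    """
    if isinstance(gm_25_by_pft, pd.DataFrame):
        groups = {
            str(k): v["gm_25"].dropna().to_numpy(dtype=float)
            for k, v in gm_25_by_pft.groupby("pft")
        }
    else:
        groups = {str(k): np.asarray(v, dtype=float) for k, v in gm_25_by_pft.items()}

    has_band = len(getattr(fit, "bootstrap_params_", [])) > 0
    if not has_band:
        warnings.warn(
            "no confidence band available; PFT ranges use point predictions",
            stacklevel=2,
        )
    rows = []
    for pft, values in groups.items():
        values = values[np.isfinite(values)]
        if len(values) < min_n:
            continue
        q1, q3 = np.quantile(values, [0.25, 0.75])
        if has_band:
            lower_q3 = fit.predict_interval([q3])[0][0]
            upper_q1 = fit.predict_interval([q1])[1][0]
        else:
            lower_q3 = fit.predict([q3])[0]
            upper_q1 = fit.predict([q1])[0]
        rows.append(
            {
                "pft": pft,
                "n": len(values),
                "gm25_q1": q1,
                "gm25_q3": q3,
                "Lm_low_percent": int(round(lower_q3)),
                "Lm_high_percent": int(round(upper_q1)),
            }
        )
    return pd.DataFrame(rows)
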