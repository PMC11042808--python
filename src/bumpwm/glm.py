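"""Trial-history regressions: choice GLM, bump-location regression, and
the geometric-decay reinterpretation of the long-term mean weight.

The choice model is a multivariate logistic regression

    P("s1<s2") = sigmoid( alpha * (s2_t - s1_t)
                          + sum_i w_i * (sbar_{t-i} - s1_t)
                          + w_mean * (<s>_t - s1_t) )

with ``sbar_tau`` the mean of the two stimuli of trial tau and ``<s>_t``
the running mean of all stimuli up to (and, by default, including) the
current trial.  The difficulty covariate is oriented as ``s2 - s1`` so
that a positive ``alpha`` means correct behavior.  If the true history
kernel is infinite and geometric, ``w_i = w0 * gamma^i``, the truncated
regression re-expresses the left-out tail through the mean covariate:
``w_mean`` is proportional to ``w_{h+1} / (1 - gamma)``, so it shrinks
as more lags enter the model — the weight on the long-term mean is a
disguised short-term history tail, not a separate mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import CHOICE_LT

__all__ = ["GlmFit", "build_design", "fit_choice_glm", "fit_bump_regression",
           "fit_geometric_decay", "predicted_mean_weight"]


@dataclass
class GlmFit:
    """Fitted weights of a history regression."""

    alpha: Optional[float]            # None for the bump (linear) regression
    history_weights: np.ndarray       # w_1..w_h
    mean_weight: float
    h: int
    bse: pd.Series                    # standard errors, by column name
    converged: bool
    model: str                        # "logit" | "ols"
    gamma: Optional[float] = None
    w0: Optional[float] = None

    @property
    def predicted_mean_weight(self) -> Optional[float]:
        """Extrapolated ``w_{h+1} / (1 - gamma)`` from the decay fit."""
        if self.gamma is None or not (0 < self.gamma < 1):
            return None
        w_next = self.w0 * self.gamma ** (self.h + 1)
        return predicted_mean_weight(self.gamma, w_next)


def build_design(trials: pd.DataFrame, h: int = 4,
                 include_current_in_mean: bool = True
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Response vector and covariate table for the history regressions.

    The first ``h`` trials are dropped from the response.  Covariates:
    ``diff`` = s2 - s1 (so a positive slope weight means correct
    comparisons), ``hist_i`` = (sbar_{t-i} - s1_t) for i = 1..h, and
    ``mean`` = (<s>_t - s1_t) with the running mean over both stimuli of
    all trials up to the current one (inclusive by default).
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    if h >= len(trials):
        raise ValueError("h must be smaller than the number of trials")
    d = trials.reset_index(drop=True)
    sbar = (d["s1"] + d["s2"]) / 2.0
    cum = sbar.expanding().mean() if include_current_in_mean \
        else sbar.expanding().mean().shift(1)
    X = pd.DataFrame({"diff": d["s2"] - d["s1"]})
    for i in range(1, h + 1):
        X[f"hist_{i}"] = sbar.shift(i) - d["s1"]
    X["mean"] = cum - d["s1"]
    y = (d["choice"] == CHOICE_LT).astype(float)
    keep = X.notna().all(axis=1)
    keep.iloc[:h] = False
    return y[keep], X[keep]


def _check_rank(X: pd.DataFrame) -> bool:
    return np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]


def fit_choice_glm(y: pd.Series, X: pd.DataFrame, h: Optional[int] = None,
                   fit_decay: bool = True) -> GlmFit:
    """Maximum-likelihood logistic fit, unregularized.

    Separation or rank deficiency is reported through ``converged``
    rather than silently penalized.
    """
    if not _check_rank(X):
        raise ValueError("design matrix is rank deficient "
                         "(constant stimulus sequence?)")
    hist_cols = [c for c in X.columns if c.startswith("hist_")]
    h = h or len(hist_cols)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        res = model.fit(disp=0, method="bfgs", maxiter=500)
        converged = bool(res.mle_retvals.get("converged", False))
    w = res.params[hist_cols].to_numpy()
    fit = GlmFit(alpha=float(res.params["diff"]), history_weights=w,
                 mean_weight=float(res.params["mean"]), h=h,
                 bse=res.bse, converged=converged, model="logit")
    if fit_decay:
        _attach_decay(fit)
    return fit


def fit_bump_regression(trials: pd.DataFrame, h: int = 4,
                        loc_column: str = "wm_loc_pre",
                        fit_decay: bool = True) -> GlmFit:
    """OLS of the bump displacement on the same history covariates.

    The regressand is ``loc - s1`` (the displacement of the stored value
    from the true first stimulus); the difficulty covariate is absent
    because the readout precedes s2.
    """
    _, X = build_design(trials, h=h)
    X = X.drop(columns="diff")
    d = trials.reset_index(drop=True)
    target = (d[loc_column] - d["s1"]).loc[X.index]
    valid = target.notna()
    X, target = X[valid], target[valid]
    if not _check_rank(X):
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(target, X).fit()
    hist_cols = [c for c in X.columns if c.startswith("hist_")]
    fit = GlmFit(alpha=None, history_weights=res.params[hist_cols].to_numpy(),
                 mean_weight=float(res.params["mean"]), h=h,
                 bse=res.bse, converged=True, model="ols")
    if fit_decay:
        _attach_decay(fit)
    return fit


def fit_geometric_decay(history_weights: np.ndarray) -> tuple[float, float]:
    """Fit ``w_i = w0 * gamma^i`` by log-linear least squares.

    Requires at least three lags of consistent sign; alternating signs
    are refused because the log-linear model is undefined there.
    """
    w = np.asarray(history_weights, dtype=float)
    if w.size < 3:
        raise ValueError("need at least three history weights")
    signs = np.sign(w[w != 0])
    if signs.size == 0 or not (np.all(signs > 0) or np.all(signs < 0)):
        raise ValueError("history weights must share a sign for a decay fit")
    lags = np.arange(1, w.size + 1)
    logw = np.log(np.abs(w))
    slope, intercept = np.polyfit(lags, logw, 1)
    gamma = float(np.exp(slope))
    w0 = float(np.exp(intercept)) * (1.0 if signs[0] > 0 else -1.0)
    return gamma, w0


def predicted_mean_weight(gamma: float, w_next: float) -> float:
    """Mean-covariate weight implied by the left-out geometric tail."""
    if not (0 < gamma < 1):
        raise ValueError("gamma must be in (0, 1)")
    return w_next / (1.0 - gamma)


def _attach_decay(fit: GlmFit) -> None:
    try:
        fit.gamma, fit.w0 = fit_geometric_decay(fit.history_weights)
    except ValueError:
        fit.gamma, fit.w0 = None, None
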