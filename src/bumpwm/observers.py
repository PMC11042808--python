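"""Trial-level observer models of contraction bias.

Two accounts of the same behavior are implemented and can be fitted to
the same empirical performance curves:

*Replacement (statistical) observer.*  The comparison is perfect except
that, with probability ``epsilon``, the memory of the first stimulus is
replaced by a draw from a buffer distribution ``p_m`` (in the circuit:
the posterior-parietal bump location, whose distribution tracks the
marginal stimulus distribution).  The error probability of a pair is
then ``epsilon`` times the ``p_m`` mass on the wrong side of s2, with
half weight on a replacement that ties s2 exactly (resolved by a fair
coin).  An optional symmetric lapse ``delta`` mixes in random choices.

*Bayesian ideal observer.*  The first stimulus is encoded as
``r1 ~ Normal(s1, sigma)``; the second is noiseless.  The observer
reports "s1<s2" when the posterior mass below s2 (prior = the stimulus
distribution) exceeds 1/2.  The Gaussian location likelihood has a
monotone likelihood ratio, so the report region is a half-line
``r1 < r*`` and the response probability is an exact Gaussian tail
integral once the threshold ``r*`` is found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .stimdist import StimulusDistribution

__all__ = ["StatObserver", "BayesObserver", "ObserverFit",
           "error_probability", "predict_performance_curves",
           "bayes_response_prob", "fit_observer"]


@dataclass(frozen=True)
class StatObserver:
    """Epsilon-replacement observer with lapse."""

    epsilon: float
    replacement_dist: StimulusDistribution
    lapse: float = 0.0

    def __post_init__(self):
        if not (0 <= self.epsilon <= 1 and 0 <= self.lapse <= 1):
            raise ValueError("epsilon and lapse must be in [0, 1]")


@dataclass(frozen=True)
class BayesObserver:
    """Gaussian-likelihood ideal observer; the second stimulus is exact."""

    sigma1: float
    prior: StimulusDistribution
    lapse: float = 0.0
    sigma2: float = 0.0   # fixed: no uncertainty on s2

    def __post_init__(self):
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.sigma2 != 0.0:
            raise ValueError("only the sigma2 = 0 reduction is implemented")


def replacement_error_core(s1: float, s2: float,
                           dist: StimulusDistribution) -> float:
    """Probability that a replacement draw lands on the wrong side of s2.

    Wrong side = above s2 when s1 > s2, below s2 when s1 < s2; a draw
    exactly at s2 counts half (fair-coin tie).  ``s2`` must be on the
    support grid — off-grid values are refused rather than interpolated.
    """
    if s1 == s2:
        raise ValueError("s1 == s2 is not a valid comparison trial")
    try:
        half_tie = dist.pm(s2) / 2.0
        below = dist.cdf_below(s2)
        above = dist.cdf_above(s2)
    except ValueError:
        # s2 between grid points: no tie mass.  Allowed only on a uniform
        # grid, where "below/above s2" is unambiguous; a nonuniform grid
        # would need an interpolation model, which is refused.
        spacing = np.diff(dist.support)
        if not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValueError(
                f"s2={s2} off the (nonuniform) support grid; refusing to "
                "interpolate") from None
        half_tie = 0.0
        below = float(dist.probs[dist.support < s2].sum())
        above = float(dist.probs[dist.support > s2].sum())
    if s1 > s2:
        return half_tie + below
    return half_tie + above


def error_probability(s1: float, s2: float, observer: StatObserver) -> float:
    """Total error probability of the replacement observer for one pair.

    ``(1 - lapse) * epsilon * wrong_side_mass + lapse / 2``.
    """
    p_e = observer.epsilon * replacement_error_core(s1, s2, observer.replacement_dist)
    return (1.0 - observer.lapse) * p_e + observer.lapse / 2.0


def predict_performance_curves(stim_pairs: Iterable[tuple[float, float]],
                               observer) -> pd.DataFrame:
    """Accuracy vs s1, split by the side of the s1 = s2 diagonal.

    Works for both observer types.  Returns columns
    ``s1, s2, side ('s1>s2' | 's1<s2'), accuracy``.
    """
    rows = []
    for s1, s2 in stim_pairs:
        if isinstance(observer, StatObserver):
            acc = 1.0 - error_probability(s1, s2, observer)
        else:
            p_lt = bayes_response_prob(s1, s2, observer)
            acc = p_lt if s1 < s2 else 1.0 - p_lt
            acc = (1.0 - observer.lapse) * acc + observer.lapse / 2.0
        rows.append({"s1": s1, "s2": s2,
                     "side": "s1>s2" if s1 > s2 else "s1<s2",
                     "accuracy": acc})
    return pd.DataFrame(rows).sort_values(["side", "s1"]).reset_index(drop=True)


def _posterior_mass_below(r1: float, s2: float, prior: StimulusDistribution,
                          sigma: float) -> float:
    """Posterior mass below s2 given representation r1 (half mass at s2)."""
    z2 = ((prior.support - r1) / sigma) ** 2
    w = prior.probs * np.exp(-0.5 * (z2 - z2.min()))
    total = w.sum()
    if total == 0:
        # numerically degenerate: posterior collapses onto nearest support
        nearest = np.argmin(np.abs(prior.support - r1))
        below = prior.support[nearest] < s2
        at = prior.support[nearest] == s2
        return 1.0 if below else (0.5 if at else 0.0)
    below = w[prior.support < s2].sum()
    at = w[np.isclose(prior.support, s2)].sum()
    return float((below + 0.5 * at) / total)


def bayes_response_prob(s1: float, s2: float, observer: BayesObserver) -> float:
    """P("s1<s2" | s1, s2) of the ideal observer, computed exactly.

    The posterior mass below s2 is non-increasing in r1 (monotone
    likelihood ratio of the Gaussian location family), so the decision
    region is ``r1 < r*``; the threshold is located by bisection and the
    answer is the Gaussian tail ``Phi((r* - s1) / sigma)``.
    """
    prior, sigma = observer.prior, observer.sigma1
    lo = float(prior.support[0] - 40.0 * sigma - 1.0)
    hi = float(prior.support[-1] + 40.0 * sigma + 1.0)
    f = lambda r: _posterior_mass_below(r, s2, prior, sigma) - 0.5
    f_lo, f_hi = f(lo), f(hi)
    if f_lo <= 0:        # even the lowest representation says "above"
        return 0.0 if f_hi <= 0 else 1.0
    if f_hi > 0:         # always below
        return 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13 * max(1.0, abs(hi)):
            break
    r_star = 0.5 * (lo + hi)
    return float(ndtr((r_star - s1) / sigma))


def bayes_response_prob_quadrature(s1: float, s2: float,
                                   observer: BayesObserver,
                                   n_grid: int = 2001) -> float:
    """Fixed-grid quadrature of the same integral (cross-check path)."""
    prior, sigma = observer.prior, observer.sigma1
    lo = min(prior.support[0], s1) - 6.0 * sigma
    hi = max(prior.support[-1], s1) + 6.0 * sigma
    grid = np.linspace(lo, hi, n_grid)
    pdf = np.exp(-0.5 * ((grid - s1) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    ind = np.array([_posterior_mass_below(r, s2, prior, sigma) > 0.5 for r in grid])
    return float(np.trapezoid(pdf * ind, grid))


@dataclass
class ObserverFit:
    """Result of fitting one observer model to empirical accuracy curves."""

    model: str
    params: dict
    loss: float
    predictions: pd.DataFrame
    non_identifiable: bool = False


def _empirical_curves(curves: pd.DataFrame) -> pd.DataFrame:
    need = {"s1", "s2", "accuracy"}
    if not need.issubset(curves.columns):
        raise ValueError(f"curves must have columns {need}")
    return curves


def _fit_stat(curves: pd.DataFrame, dist: StimulusDistribution,
              fit_lapse: bool, lapse_grid: np.ndarray) -> ObserverFit:
    acc = curves["accuracy"].to_numpy()
    core = np.array([replacement_error_core(r.s1, r.s2, dist)
                     for r in curves.itertuples()])
    if np.allclose(core, core[0]):
        return ObserverFit("stat", {"epsilon": np.nan, "lapse": np.nan},
                           np.nan, curves.copy(), non_identifiable=True)
    best = None
    grid = lapse_grid if fit_lapse else np.array([0.0])
    for delta in grid:
        # accuracy model: (1-delta)(1 - eps*core) + delta/2, linear in eps
        target = 1.0 - delta / 2.0 - acc
        x = (1.0 - delta) * core
        eps = float(np.clip((x @ target) / (x @ x), 0.0, 1.0))
        pred = (1.0 - delta) * (1.0 - eps * core) + delta / 2.0
        loss = float(np.mean((acc - pred) ** 2))
        if best is None or loss < best[0]:
            best = (loss, eps, float(delta), pred)
    loss, eps, delta, pred = best
    out = curves.copy()
    out["predicted"] = pred
    return ObserverFit("stat", {"epsilon": eps, "lapse": delta}, loss, out)


def _fit_bayes(curves: pd.DataFrame, dist: StimulusDistribution,
               sigma_grid: np.ndarray) -> ObserverFit:
    acc = curves["accuracy"].to_numpy()
    pairs = list(zip(curves["s1"], curves["s2"]))

    def loss_at(sigma: float) -> tuple[float, np.ndarray]:
        obs = BayesObserver(sigma1=sigma, prior=dist)
        pred = predict_performance_curves(pairs, obs)
        # align to input order
        p = np.array([
            pred[(pred.s1 == a) & (pred.s2 == b)]["accuracy"].iloc[0]
            for a, b in pairs])
        return float(np.mean((acc - p) ** 2)), p

    evals = [(s, *loss_at(s)) for s in sigma_grid]
    evals.sort(key=lambda t: t[1])
    s0 = evals[0][0]
    # local refinement around the best grid point
    fine = np.geomspace(max(s0 / 1.6, 1e-4), s0 * 1.6, 13)
    evals_f = [(s, *loss_at(s)) for s in fine]
    evals_f.sort(key=lambda t: t[1])
    sigma, loss, pred = evals_f[0]
    out = curves.copy()
    out["predicted"] = pred
    return ObserverFit("bayes", {"sigma": float(sigma)}, loss, out)


def fit_observer(curves: pd.DataFrame, model: str,
                 distribution: StimulusDistribution,
                 fit_lapse: bool = False,
                 lapse_grid: Optional[np.ndarray] = None,
                 sigma_grid: Optional[np.ndarray] = None) -> ObserverFit:
    """Fit an observer to empirical per-pair accuracies by minimum MSE.

    For the replacement model the MSE is quadratic in epsilon at fixed
    lapse, so epsilon is solved in closed form on a lapse grid; for the
    Bayesian model a geometric sigma grid with local refinement is used.
    """
    curves = _empirical_curves(curves)
    if model == "stat":
        if lapse_grid is None:
            lapse_grid = np.arange(0.0, 0.2001, 0.0025)
        return _fit_stat(curves, distribution, fit_lapse, lapse_grid)
    if model == "bayes":
        if sigma_grid is None:
            sigma_grid = np.geomspace(0.01, 1.0, 25)
        return _fit_bayes(curves, distribution, sigma_grid)
    raise ValueError("model must be 'stat' or 'bayes'")


def empirical_accuracy_curves(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-pair accuracy table in the shape ``fit_observer`` expects."""
    ok = trials.dropna(subset=["correct"])
    ok = ok[~ok["is_psychometric"]] if "is_psychometric" in ok else ok
    out = (ok.groupby(["s1", "s2"])["correct"].agg(["mean", "size"])
           .rename(columns={"mean": "accuracy", "size": "n"}).reset_index())
    return out
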