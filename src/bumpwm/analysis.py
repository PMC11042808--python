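"""Behavioral statistics for delayed-comparison trial tables.

All functions consume the shared trial-table schema (one row per trial,
time-ordered within a session; an optional ``session`` column separates
independent sessions) and quantify the phenomena of interest: per-pair
performance, psychometric curves, contraction bias, n-back serial
dependence, bump-origin fractions with analytic chance levels, and
continuous-recall bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .stimdist import StimulusDistribution
from .task import CHOICE_LT

__all__ = [
    "BiasSummary", "performance_matrix", "psychometric_curve",
    "contraction_bias_score", "history_bias_slope", "bump_origin_fractions",
    "recall_analysis",
]


def _sessions(trials: pd.DataFrame) -> pd.Series:
    if "session" in trials.columns:
        return trials["session"]
    return pd.Series(0, index=trials.index)


def _lagged(trials: pd.DataFrame, col: str, lag: int) -> pd.Series:
    """Lag a column within sessions (no leakage across session breaks)."""
    return trials.groupby(_sessions(trials))[col].shift(lag)


def _resp_lt(trials: pd.DataFrame) -> pd.Series:
    return (trials["choice"] == CHOICE_LT).astype(float)


# ---------------------------------------------------------------------------


def performance_matrix(trials: pd.DataFrame) -> pd.DataFrame:
    """Per stimulus pair: fraction judged "s1<s2", accuracy, trial count.

    Pairs never presented are simply absent from the index (missing, not
    zero).  Trials with no valid choice are excluded from both fractions.
    """
    ok = trials.dropna(subset=["correct"])
    if ok.empty:
        raise ValueError("no valid trials")
    grp = ok.assign(resp_lt=_resp_lt(ok)).groupby(["s1", "s2"])
    out = grp.agg(frac_lt=("resp_lt", "mean"),
                  accuracy=("correct", "mean"),
                  n=("correct", "size"))
    return out


def psychometric_curve(trials: pd.DataFrame, by_delay: bool = True,
                       min_n: int = 20) -> pd.DataFrame:
    """Fraction "s1<s2" versus the signed difficulty s2 - s1.

    Uses psychometric trials only.  Returns one row per (delay, offset)
    with the response fraction, count, a ``low_n`` flag for delay levels
    with fewer than ``min_n`` trials, and the midpoint slope of the
    curve (least-squares slope of fraction vs offset) per delay.
    """
    psy = trials[trials["is_psychometric"]].dropna(subset=["correct"]).copy()
    if psy.empty:
        raise ValueError("no psychometric trials in table")
    psy["offset"] = psy["s2"] - psy["s1"]
    psy["resp_lt"] = _resp_lt(psy)
    keys = ["delay", "offset"] if by_delay else ["offset"]
    curve = psy.groupby(keys).agg(frac_lt=("resp_lt", "mean"),
                                  n=("resp_lt", "size")).reset_index()
    if not by_delay:
        curve["delay"] = np.nan
    slopes, flags = {}, {}
    for delay, g in curve.groupby("delay", dropna=False):
        n_tot = g["n"].sum()
        flags[delay] = n_tot < min_n
        if g["offset"].nunique() >= 2:
            slope = np.polyfit(g["offset"], g["frac_lt"], 1, w=g["n"])[0]
        else:
            slope = np.nan
        slopes[delay] = slope
    curve["midpoint_slope"] = curve["delay"].map(slopes)
    curve["low_n"] = curve["delay"].map(flags)
    return curve


def contraction_bias_score(trials: pd.DataFrame,
                           mean_stim: float) -> tuple[float, float]:
    """Relative performance of Bias+ and Bias- trial classes.

    A pair is Bias+ when contraction of the remembered s1 toward
    ``mean_stim`` moves it *away* from s2 (helping the comparison), i.e.
    ``(mean_stim - s1) * (s1 - s2) > 0``, and Bias- for the opposite
    sign.  Pairs with s1 exactly at the mean belong to neither class.
    Returns mean accuracy of each class minus the grand mean accuracy.
    """
    ok = trials.dropna(subset=["correct"])
    ok = ok[~ok["is_psychometric"]] if "is_psychometric" in ok else ok
    cls = np.sign((mean_stim - ok["s1"]) * (ok["s1"] - ok["s2"]))
    grand = ok["correct"].mean()
    plus = ok.loc[cls > 0, "correct"].mean() - grand
    minus = ok.loc[cls < 0, "correct"].mean() - grand
    return float(plus), float(minus)


@dataclass
class BiasSummary:
    """n-back serial-dependence summary.

    ``pooled_slope`` is the least-squares slope of the within-pair
    de-meaned response fraction against the lag-n pair mean; negative
    values mean attraction toward past stimuli.
    """

    n_back: int
    pooled_slope: float
    ci_low: float
    ci_high: float
    per_pair_slopes: pd.DataFrame
    n_trials: int
    degenerate: bool = False

    @property
    def excludes_zero(self) -> bool:
        return (self.ci_low > 0) or (self.ci_high < 0)

    @property
    def covers_zero(self) -> bool:
        return self.ci_low <= 0 <= self.ci_high


def _pooled_slope(resp_dm: np.ndarray, prev_mean: np.ndarray) -> float:
    x = prev_mean - prev_mean.mean()
    denom = (x ** 2).sum()
    if denom == 0:
        return np.nan
    return float((x * resp_dm).sum() / denom)


def history_bias_slope(trials: pd.DataFrame, n_back: int = 1,
                       n_boot: int = 1000, seed: int = 0) -> BiasSummary:
    """Attraction of the current choice toward the lag-n stimulus pair.

    For each current pair, the fraction of "s1<s2" responses is de-meaned
    and regressed on the mean ``(s1 + s2)/2`` of the pair presented
    ``n_back`` trials earlier.  A percentile bootstrap over trials gives
    the CI of the pooled (count-weighted) slope.
    """
    if n_back < 1:
        raise ValueError("n_back must be >= 1")
    d = trials.copy()
    d["resp_lt"] = _resp_lt(d)
    d["prev_mean"] = (_lagged(d, "s1", n_back) + _lagged(d, "s2", n_back)) / 2.0
    d = d.dropna(subset=["correct", "prev_mean"])
    if d.empty or d["prev_mean"].nunique() < 2:
        return BiasSummary(n_back, np.nan, np.nan, np.nan,
                           pd.DataFrame(), len(d), degenerate=True)
    d["resp_dm"] = d.groupby(["s1", "s2"])["resp_lt"].transform(lambda x: x - x.mean())

    per_pair = []
    for (s1, s2), g in d.groupby(["s1", "s2"]):
        if g["prev_mean"].nunique() >= 2:
            per_pair.append({"s1": s1, "s2": s2, "n": len(g),
                             "slope": _pooled_slope(g["resp_dm"].to_numpy(),
                                                    g["prev_mean"].to_numpy())})
    per_pair = pd.DataFrame(per_pair)

    point = _pooled_slope(d["resp_dm"].to_numpy(), d["prev_mean"].to_numpy())
    rng = np.random.default_rng(seed)
    resp = d["resp_lt"].to_numpy()
    prev = d["prev_mean"].to_numpy()
    pair_codes = pd.factorize(d["s1"].astype(str) + "|" + d["s2"].astype(str))[0]
    n = len(d)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        r, p, c = resp[idx], prev[idx], pair_codes[idx]
        means = np.bincount(c, weights=r) / np.maximum(np.bincount(c), 1)
        boots[b] = _pooled_slope(r - means[c], p)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return BiasSummary(n_back, point, float(lo), float(hi), per_pair, n)


_ORIGIN_TARGETS = ("s1_t", "s2_t-1", "s1_t-1", "s2_t-2", "s1_t-2", "mean")


def bump_origin_fractions(trials: pd.DataFrame,
                          distribution: StimulusDistribution,
                          window: float = 0.05,
                          loc_column: str = "wm_loc_pre") -> pd.DataFrame:
    """Fraction of trials whose bump sits at each candidate origin.

    For every target (current s1, the stimuli of the one and two
    preceding trials, and the distribution mean) the fraction of trials
    with ``|loc - target| <= window`` is reported together with the
    analytic chance level: ``sum_i p_m(i)^2`` for stimulus targets (the
    collision probability of two independent draws from the marginal)
    and ``p_m(mean)`` for the deterministic mean target.  The median
    target is reported as well, which matters for skewed distributions.
    """
    d = trials.copy()
    loc = d[loc_column]
    targets = {
        "s1_t": d["s1"],
        "s2_t-1": _lagged(d, "s2", 1), "s1_t-1": _lagged(d, "s1", 1),
        "s2_t-2": _lagged(d, "s2", 2), "s1_t-2": _lagged(d, "s1", 2),
        "mean": pd.Series(distribution.mean, index=d.index),
        "median": pd.Series(distribution.median, index=d.index),
    }
    coll = distribution.collision_probability()

    def chance_at(v: float) -> float:
        try:
            return distribution.pm(v)
        except ValueError:
            return 0.0

    rows = []
    for name, tgt in targets.items():
        valid = loc.notna() & tgt.notna()
        frac = (np.abs(loc[valid] - tgt[valid]) <= window).mean() if valid.any() else np.nan
        chance = coll if name not in ("mean", "median") else chance_at(tgt.iloc[0])
        rows.append({"target": name, "fraction": float(frac),
                     "chance": float(chance), "n": int(valid.sum())})
    return pd.DataFrame(rows).set_index("target")


def shuffle_origin_fraction(trials: pd.DataFrame, target: pd.Series,
                            n_perm: int = 200, window: float = 0.05,
                            loc_column: str = "wm_loc_pre",
                            seed: int = 0) -> float:
    """Permutation estimate of the chance fraction for one target series."""
    rng = np.random.default_rng(seed)
    loc = trials[loc_column].to_numpy()
    tgt = np.asarray(target, dtype=float)
    valid = ~(np.isnan(loc) | np.isnan(tgt))
    loc, tgt = loc[valid], tgt[valid]
    fracs = np.empty(n_perm)
    for i in range(n_perm):
        fracs[i] = (np.abs(rng.permutation(loc) - tgt) <= window).mean()
    return float(fracs.mean())


def recall_analysis(trials: pd.DataFrame,
                    displacement_bins: Optional[np.ndarray] = None) -> dict:
    """Continuous-recall diagnostics from the end-of-delay bump position.

    Returns the identity-departure curve (mean recalled position vs s1,
    per delay), the distribution of the recall displacement
    ``loc_end - s1`` conditioned on the previous trial's s2, and the
    attraction slope: the least-squares slope of the displacement
    against ``s1_t - s2_{t-1}`` (negative = attraction), per delay and
    pooled.
    """
    d = trials.copy()
    d["displacement"] = d["wm_loc_end_delay"] - d["s1"]
    d["s2_prev"] = _lagged(d, "s2", 1)
    d["dist_prev"] = d["s1"] - d["s2_prev"]
    d = d.dropna(subset=["wm_loc_end_delay"])

    curve = (d.groupby(["delay", "s1"])["wm_loc_end_delay"]
             .agg(["mean", "size"]).reset_index()
             .rename(columns={"mean": "recall_mean", "size": "n"}))

    v = d.dropna(subset=["dist_prev"])
    slopes = {}
    for delay, g in v.groupby("delay"):
        if g["dist_prev"].nunique() >= 2:
            slopes[float(delay)] = float(np.polyfit(g["dist_prev"], g["displacement"], 1)[0])
    pooled = (float(np.polyfit(v["dist_prev"], v["displacement"], 1)[0])
              if v["dist_prev"].nunique() >= 2 else np.nan)

    if displacement_bins is None:
        displacement_bins = np.linspace(-1, 1, 41)
    hists = {}
    for s2p, g in v.groupby("s2_prev"):
        hist, _ = np.histogram(g["displacement"], bins=displacement_bins)
        hists[float(s2p)] = hist
    return {"identity_curve": curve, "attraction_slope": slopes,
            "attraction_slope_pooled": pooled,
            "displacement_hists": hists, "bins": displacement_bins}
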