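"""Synthetic 2AFC session generator with planted statistical structure.

Emulates the human delayed-comparison protocol — pairs around the
diagonal, delays drawn from {2, 4, 6} s, ~400 self-paced trials with a
bimodal inter-trial-interval distribution — while planting the exact
statistical mechanisms the analysis stack is designed to detect:

* epsilon-replacement of the remembered s1 from the marginal stimulus
  distribution, with the replacement probability modulated
  logistic-linearly upward by delay and downward by ITI;
* an explicit serial-dependence kernel ``q_k``: with probability q_k
  the replacement is the second stimulus from k trials back instead of
  a fresh marginal draw;
* a symmetric lapse rate.

Every planted parameter is recoverable by the corresponding estimator
(observer fits, history-bias slope, GLM), which makes the generator the
ground truth for end-to-end tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import lognorm

from .stimdist import StimulusDistribution, make_distribution
from .task import CHOICE_GT, CHOICE_LT, TRIAL_COLUMNS, generate_stimulus_set

__all__ = ["GeneratorSpec", "ItiModel", "iti_sampler", "sample_session",
           "make_distribution"]


@dataclass(frozen=True)
class ItiModel:
    """Bimodal positive mixture for self-paced inter-trial intervals.

    Two lognormal components: a short mode (~1 s; quick re-engagement)
    and a long mode (> 3 s; breaks), mixed with ``short_weight``.  The
    3 s boundary splits the two modes, mirroring the short/long analysis
    convention.
    """

    short_mode: float = 1.0
    long_mode: float = 5.5
    short_sigma: float = 0.35
    long_sigma: float = 0.35
    short_weight: float = 0.55

    def _components(self):
        # lognormal with median at the requested mode scale
        return (lognorm(self.short_sigma, scale=self.short_mode),
                lognorm(self.long_sigma, scale=self.long_mode))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        short, long_ = self._components()
        pick = rng.random(size) < self.short_weight
        out = np.where(pick, short.rvs(size=size, random_state=rng),
                       long_.rvs(size=size, random_state=rng))
        return out

    def pdf(self, x) -> np.ndarray:
        short, long_ = self._components()
        return (self.short_weight * short.pdf(x)
                + (1 - self.short_weight) * long_.pdf(x))


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything the synthetic generator needs, with protocol defaults."""

    distribution: StimulusDistribution = field(
        default_factory=lambda: make_distribution("uniform"))
    n_trials: int = 400
    delays: Sequence[float] = (2.0, 4.0, 6.0)
    iti_model: ItiModel = field(default_factory=ItiModel)
    epsilon_base: float = 0.3
    delay_gain: float = 0.0       # d(logit eps)/d(delay - mean delay)
    iti_gain: float = 0.0         # -d(logit eps)/d(iti - 3)
    history_kernel: Sequence[float] = ()   # q_1..q_K
    lapse: float = 0.0
    diagonal_offset: float = 0.1
    psychometric_fraction: float = 0.0
    psychometric_offsets: Sequence[float] = (-0.08, -0.04, -0.02, 0.02, 0.04, 0.08)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.epsilon_base <= 1 and 0 <= self.lapse <= 1):
            raise ValueError("epsilon_base and lapse must be in [0, 1]")
        if sum(self.history_kernel) > 1.0 + 1e-12:
            raise ValueError("history kernel probabilities must sum to <= 1")

    def epsilon(self, delay: float, iti: float) -> float:
        """Replacement probability, logistic-linear in delay and ITI."""
        if self.delay_gain == 0 and self.iti_gain == 0:
            return self.epsilon_base
        base = np.clip(self.epsilon_base, 1e-9, 1 - 1e-9)
        mean_delay = float(np.mean(self.delays))
        z = logit(base) + self.delay_gain * (delay - mean_delay) \
            - self.iti_gain * (iti - 3.0)
        return float(expit(z))

    def to_json(self) -> str:
        d = asdict(self)
        d["distribution"] = {"support": list(self.distribution.support),
                             "probs": list(self.distribution.probs),
                             "label": self.distribution.label}
        return json.dumps(d, indent=2, default=list)


def iti_sampler(spec: GeneratorSpec, rng: Optional[np.random.Generator] = None,
                size: int = 1) -> np.ndarray:
    """Draw self-paced inter-trial intervals from the bimodal mixture."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return spec.iti_model.sample(rng, size)


def sample_session(spec: GeneratorSpec) -> pd.DataFrame:
    """Generate one synthetic session in the shared trial-table schema.

    The remembered first stimulus is emitted as ``wm_loc_pre`` and
    ``wm_loc_end_delay`` so that recall analyses see the planted
    replacement structure; ``ppc_loc_pre`` carries the value the buffer
    would have supplied on that trial.
    """
    rng = np.random.default_rng(spec.seed)
    dist = spec.distribution
    pairs, weights = generate_stimulus_set(
        dist, spec.diagonal_offset, spec.psychometric_offsets,
        spec.psychometric_fraction)
    idx = rng.choice(len(pairs), size=spec.n_trials, p=weights)
    delays = rng.choice(spec.delays, size=spec.n_trials)
    itis = iti_sampler(spec, rng, spec.n_trials)
    q = np.asarray(spec.history_kernel, dtype=float)

    s2_hist: list[float] = []
    rows = []
    for t in range(spec.n_trials):
        s1, s2, psy = pairs[idx[t]]
        delay, iti = float(delays[t]), float(itis[t])
        eps = spec.epsilon(delay, iti)
        remembered = s1
        buffer_value = float(dist.sample(rng))
        if q.size:
            u = rng.random()
            acc = 0.0
            for k, qk in enumerate(q, start=1):
                acc += qk
                if u < acc:
                    if len(s2_hist) >= k:
                        buffer_value = s2_hist[-k]
                    break
        replaced = rng.random() < eps
        if replaced:
            remembered = buffer_value
        if remembered < s2:
            choice = CHOICE_LT
        elif remembered > s2:
            choice = CHOICE_GT
        else:
            choice = CHOICE_LT if rng.random() < 0.5 else CHOICE_GT
        if rng.random() < spec.lapse:
            choice = CHOICE_LT if rng.random() < 0.5 else CHOICE_GT
        correct = float(choice == (CHOICE_LT if s1 < s2 else CHOICE_GT))
        rows.append({
            "trial": t, "s1": s1, "s2": s2, "delay": delay, "iti": iti,
            "is_psychometric": psy, "choice": choice, "correct": correct,
            "wm_loc_pre": remembered, "wm_loc_post": s2,
            "wm_loc_end_delay": remembered, "ppc_loc_pre": buffer_value,
            "ppc_loc_start": buffer_value,
            "ppc_jump_prev": bool(replaced),
        })
        s2_hist.append(s2)
    return pd.DataFrame(rows)[TRIAL_COLUMNS]
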