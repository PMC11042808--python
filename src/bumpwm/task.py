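"""Delayed-comparison task protocol on the coupled circuit.

A session is a sequence of two-alternative forced-choice trials
``[ITI][s1 400 ms][delay][s2 400 ms]`` run on one circuit with *no state
reset between trials* — the carry-over of network state is what produces
serial dependence.  The WM activity is read out 200 ms before and 200 ms
after the onset of the second stimulus; the comparison ``which readout
is higher on the line`` is the binary choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import CoupledCircuit, has_bump, steady_bump_width
from .params import NetworkParams
from .stimdist import StimulusDistribution, make_distribution

CHOICE_LT = "s1<s2"   # response "first stimulus smaller"
CHOICE_GT = "s1>s2"

TRIAL_COLUMNS = ["trial", "s1", "s2", "delay", "iti", "is_psychometric",
                 "choice", "correct", "wm_loc_pre", "wm_loc_post",
                 "wm_loc_end_delay", "ppc_loc_pre", "ppc_loc_start",
                 "ppc_jump_prev"]

STIM_DURATION = 0.4
READOUT_OFFSET = 0.2


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial."""

    s1: float
    s2: float
    delay: float
    iti: float
    is_psychometric: bool = False

    def __post_init__(self):
        if self.s1 == self.s2:
            raise ValueError("s1 == s2 is excluded from the task")
        if self.delay <= 0 or self.iti <= 0:
            raise ValueError("delay and iti must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Protocol of a simulated session."""

    n_trials: int = 300
    design: str = "interleaved"          # interleaved | block
    delays: Sequence[float] = (2.0, 6.0, 10.0)
    iti: float = 5.0
    stimulus_distribution: Optional[StimulusDistribution] = None
    diagonal_offset: float = 0.2
    psychometric_fraction: float = 0.1
    psychometric_offsets: Sequence[float] = (-0.08, -0.04, -0.02, 0.02, 0.04, 0.08)
    ppc_coupling_scale: float = 1.0
    adaptation_on: bool = True
    tau_adapt_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.psychometric_fraction <= 1):
            raise ValueError("psychometric_fraction must be in [0, 1]")
        if not (0 <= self.ppc_coupling_scale <= 1):
            raise ValueError("ppc_coupling_scale must be in [0, 1]")
        if self.design not in ("interleaved", "block"):
            raise ValueError("design must be 'interleaved' or 'block'")

    @property
    def distribution(self) -> StimulusDistribution:
        if self.stimulus_distribution is not None:
            return self.stimulus_distribution
        # diagonal_offset 0.2 keeps every s2 inside [0.1, 0.9]; the pair
        # displacement also exceeds the bump width so that a PPC bump
        # tracking the stimuli registers as a jump.
        return make_distribution("uniform", support=np.linspace(0.3, 0.7, 5))


def generate_stimulus_set(distribution: StimulusDistribution,
                          diagonal_offset: float = 0.1,
                          psychometric_offsets: Sequence[float] = (
                              -0.08, -0.04, -0.02, 0.02, 0.04, 0.08),
                          psychometric_fraction: float = 0.1):
    """Stimulus pairs with sampling weights.

    Main pairs sit at ``|s1 - s2| = diagonal_offset`` on both sides of
    the diagonal, with the marginal of s1 following ``distribution``.
    Psychometric pairs vary the distance to the diagonal around a
    central s1 (the distribution median) and carry
    ``psychometric_fraction`` of the total weight.

    Returns
    -------
    pairs : list of (s1, s2, is_psychometric)
    weights : ndarray of sampling probabilities (sums to 1)
    """
    pairs, weights = [], []
    for s1, p in zip(distribution.support, distribution.probs):
        for sign in (-1.0, +1.0):
            s2 = s1 + sign * diagonal_offset
            if not (0.0 <= s2 <= 1.0):
                raise ValueError(
                    f"pair ({s1:.3f}, {s2:.3f}) leaves [0,1]^2; "
                    "reduce diagonal_offset or shrink the support")
            pairs.append((float(s1), float(s2), False))
            weights.append(0.5 * p)
    w = np.asarray(weights)
    w *= (1.0 - psychometric_fraction) / w.sum()
    weights = list(w)
    center = distribution.median
    for off in psychometric_offsets:
        s2 = center + off
        if not (0.0 <= s2 <= 1.0):
            raise ValueError(f"psychometric pair ({center:.3f}, {s2:.3f}) leaves [0,1]^2")
        pairs.append((float(center), float(s2), True))
        weights.append(psychometric_fraction / len(psychometric_offsets))
    return pairs, np.asarray(weights)


def sample_trials(config: SessionConfig, rng: np.random.Generator) -> list[TrialSpec]:
    """Draw the trial sequence for a session."""
    dist = config.distribution
    pairs, weights = generate_stimulus_set(
        dist, config.diagonal_offset, config.psychometric_offsets,
        config.psychometric_fraction)
    idx = rng.choice(len(pairs), size=config.n_trials, p=weights)
    if config.design == "interleaved":
        delays = rng.choice(config.delays, size=config.n_trials)
    else:  # block: a single fixed delay per session
        if len(set(config.delays)) != 1:
            raise ValueError("block design requires a single delay value")
        delays = np.full(config.n_trials, config.delays[0])
    out = []
    for i, k in enumerate(idx):
        s1, s2, psy = pairs[k]
        out.append(TrialSpec(s1=s1, s2=s2, delay=float(delays[i]),
                             iti=config.iti, is_psychometric=psy))
    return out


def decide(loc_pre: float, loc_post: float, rng: np.random.Generator) -> str:
    """Binary readout: which of the two bump positions is higher.

    Exact ties are resolved by a fair coin from the session's stream.
    ``NaN`` (no-bump) inputs propagate as ``None``.
    """
    if not (has_bump(loc_pre) and has_bump(loc_post)):
        return None
    if loc_post > loc_pre:
        return CHOICE_LT
    if loc_post < loc_pre:
        return CHOICE_GT
    return CHOICE_LT if rng.random() < 0.5 else CHOICE_GT


def detect_jumps(ppc_locations: np.ndarray, bump_width: float) -> np.ndarray:
    """Flag trials whose PPC bump moved more than one bump width.

    ``flag[t]`` is True when the PPC bump position at trial ``t`` is
    displaced by more than ``bump_width`` from trial ``t-1`` — i.e. the
    stored value was replaced at some point since the previous readout.
    The first trial is never flagged.
    """
    loc = np.asarray(ppc_locations, dtype=float)
    flags = np.zeros(loc.size, dtype=bool)
    if loc.size < 2:
        return flags
    diff = np.abs(np.diff(loc))
    flags[1:] = diff > bump_width
    flags[1:] &= ~np.isnan(diff)
    return flags


def run_session(config: SessionConfig, params_wm: NetworkParams,
                params_ppc: NetworkParams, dt: float = 0.001,
                traces_path=None) -> pd.DataFrame:
    """Simulate a full multi-trial session; returns the trial table.

    The circuit state carries over between consecutive trials.  The PPC
    to WM coupling is scaled by ``config.ppc_coupling_scale`` and
    adaptation is disabled (D = 0) when ``config.adaptation_on`` is
    False.  Trials where a readout found no bump keep a NaN position and
    a missing choice; they are retained in the table, flagged by their
    NaN entries, rather than silently dropped.
    """
    params_wm = replace(params_wm, coupling_p_to_w=params_wm.coupling_p_to_w
                        * config.ppc_coupling_scale)
    if not config.adaptation_on:
        params_ppc = replace(params_ppc, adapt_amplitude=0.0)
    if config.tau_adapt_override is not None:
        params_ppc = replace(params_ppc, tau_adapt=config.tau_adapt_override)

    rng = np.random.default_rng(config.seed)
    specs = sample_trials(config, rng)
    width = steady_bump_width(params_wm, params_ppc, dt=dt)
    circuit = CoupledCircuit(params_wm, params_ppc, dt=dt)

    trace = _TraceRecorder() if traces_path is not None else None

    rows = []
    for t, spec in enumerate(specs):
        circuit.run(spec.iti)
        if trace is not None:
            trace.snap(circuit)
        ppc_start, _ = circuit.ppc_bump()
        circuit.present(spec.s1, STIM_DURATION)
        if trace is not None:
            trace.snap(circuit)
        circuit.run(spec.delay - READOUT_OFFSET)
        wm_pre, _ = circuit.wm_bump()
        ppc_pre, _ = circuit.ppc_bump()
        if trace is not None:
            trace.snap(circuit)
        circuit.run(READOUT_OFFSET)
        wm_end, _ = circuit.wm_bump()
        circuit.present(spec.s2, READOUT_OFFSET)
        wm_post, _ = circuit.wm_bump()
        circuit.present(spec.s2, STIM_DURATION - READOUT_OFFSET)
        if trace is not None:
            trace.snap(circuit)
        choice = decide(wm_pre, wm_post, rng)
        correct = (np.nan if choice is None else
                   float(choice == (CHOICE_LT if spec.s1 < spec.s2 else CHOICE_GT)))
        rows.append({
            "trial": t, "s1": spec.s1, "s2": spec.s2, "delay": spec.delay,
            "iti": spec.iti, "is_psychometric": spec.is_psychometric,
            "choice": choice if choice is not None else "",
            "correct": correct, "wm_loc_pre": wm_pre, "wm_loc_post": wm_post,
            "wm_loc_end_delay": wm_end, "ppc_loc_pre": ppc_pre,
            "ppc_loc_start": ppc_start,
        })
    df = pd.DataFrame(rows)
    if trace is not None:
        trace.save(traces_path, params_wm, params_ppc, dt)
    # A trial is "post-jump" when the PPC content was replaced during the
    # *previous* trial: compare this trial's start-of-trial bump with the
    # previous trial's mid-delay readout.  A fresh (non-adapted) PPC bump
    # exerts the strongest pull on the WM network.
    prev_mid = np.r_[np.nan, df["ppc_loc_pre"].to_numpy()[:-1]]
    moved = np.abs(df["ppc_loc_start"].to_numpy() - prev_mid) > width
    df["ppc_jump_prev"] = moved & ~np.isnan(prev_mid)
    return df[TRIAL_COLUMNS]


class _TraceRecorder:
    """Down-sampled rate snapshots (one per trial phase) for HDF5 dump."""

    def __init__(self):
        self.wm, self.ppc, self.t = [], [], []

    def snap(self, circuit: CoupledCircuit) -> None:
        self.wm.append(circuit.rate_wm)
        self.ppc.append(circuit.rate_ppc)
        self.t.append(circuit.time)

    def save(self, path, params_wm: NetworkParams, params_ppc: NetworkParams,
             dt: float) -> None:
        import h5py

        from .params import dump_config
        with h5py.File(path, "w") as fh:
            fh.create_dataset("wm/rates", data=np.asarray(self.wm))
            fh.create_dataset("ppc/rates", data=np.asarray(self.ppc))
            fh.create_dataset("time", data=np.asarray(self.t))
            import json
            fh.attrs["config"] = json.dumps(dump_config(params_wm, params_ppc, dt))


def save_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df
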