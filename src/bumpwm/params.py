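"""Parameters and state containers for the coupled rate-network model.

Two one-dimensional line attractors are simulated: a fast working-memory
(WM) network and a slower posterior-parietal (PPC) network whose neurons
carry an adaptive firing threshold.  Neuron ``i`` of an ``N``-neuron
network has firing field ``x_i = i / N`` on the unit line; recurrent
excitation decays exponentially with firing-field distance (range
``d_0``) and inhibition is uniform.

The default numeric values shipped here were produced by the calibration
routine in :mod:`bumpwm.calibrate`, which searches for a parameter set
satisfying three qualitative constraints: (i) an isolated WM bump
self-sustains for at least 10 s, (ii) a single 400 ms stimulus displaces
the WM bump but not an established PPC bump, and (iii) the PPC operates
in the drift regime at ``tau_adapt = 7.5 s``, ``adapt_amplitude = 0.3``.
Because recurrent input sums over ~``N * d_0`` active neighbours, the
synaptic amplitudes scale as ``1/N``; :func:`default_wm_params` and
:func:`default_ppc_params` apply that scaling so any network size keeps
the same bump physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import yaml

#: Reference network size at which the defaults were calibrated.
REFERENCE_N = 300

#: Calibrated synaptic constants at ``REFERENCE_N`` (input units).
_CAL = {
    "gain": 4.615384615384615,   # beta
    "exc_amplitude": 0.00377,    # J_e
    "inhibition": 0.0010855,     # J_0
    "kernel_range": 0.05,        # d_0
    "stim_halfwidth": 0.03,      # delta_s
    "tau_wm": 0.05,              # tau_h of the WM network (s)
    "tau_ppc": 2.0,              # tau_h of the PPC network (s)
    "tau_adapt": 7.5,            # tau_theta of the PPC (s)
    "adapt_amplitude": 0.3,      # D of the PPC
    "coupling_p_to_w": 2.925,    # J_{P->W}
    "h_init": -10.0 / 4.615384615384615,   # initial input, ~ r = 0
}

DEFAULT_DT = 0.001


@dataclass(frozen=True)
class NetworkParams:
    """All constants of one rate network.

    ``tau_adapt`` and ``adapt_amplitude`` are ``None`` for the WM network
    (no adaptation) and must both be present for the PPC network.
    """

    n_neurons: int
    gain: float                      # beta
    exc_amplitude: float             # J_e
    inhibition: float                # J_0
    kernel_range: float              # d_0, fraction of attractor length
    tau_input: float                 # tau_h, seconds
    stim_halfwidth: float            # delta_s, fraction of attractor length
    tau_adapt: Optional[float] = None        # tau_theta, seconds (PPC only)
    adapt_amplitude: Optional[float] = None  # D (PPC only)
    coupling_p_to_w: float = 0.0     # J_{P->W}; meaningful on the WM side
    h_init: float = _CAL["h_init"]

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.tau_input <= 0:
            raise ValueError("tau_input must be positive")
        if not (0 < self.kernel_range < 1):
            raise ValueError("kernel_range must be in (0, 1)")
        if not (0 <= self.stim_halfwidth < 0.5):
            raise ValueError("stim_halfwidth must be in [0, 0.5)")
        if (self.tau_adapt is None) != (self.adapt_amplitude is None):
            raise ValueError("tau_adapt and adapt_amplitude must be set together")
        if self.tau_adapt is not None and self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be positive")

    @property
    def has_adaptation(self) -> bool:
        return self.tau_adapt is not None

    @property
    def firing_fields(self) -> np.ndarray:
        """x_i = i / N for i = 0..N-1."""
        return np.arange(self.n_neurons) / self.n_neurons


def _scale(n_neurons: int) -> float:
    return REFERENCE_N / n_neurons


def default_wm_params(n_neurons: int = REFERENCE_N,
                      coupling_scale: float = 1.0) -> NetworkParams:
    """Calibrated WM-network parameters, rescaled to ``n_neurons``.

    ``coupling_scale`` multiplies J_{P->W}; 1 is the intact circuit and 0
    mimics full PPC inactivation.
    """
    k = _scale(n_neurons)
    return NetworkParams(
        n_neurons=n_neurons,
        gain=_CAL["gain"],
        exc_amplitude=_CAL["exc_amplitude"] * k,
        inhibition=_CAL["inhibition"] * k,
        kernel_range=_CAL["kernel_range"],
        tau_input=_CAL["tau_wm"],
        stim_halfwidth=_CAL["stim_halfwidth"],
        coupling_p_to_w=_CAL["coupling_p_to_w"] * coupling_scale,
    )


def default_ppc_params(n_neurons: int = REFERENCE_N,
                       tau_adapt: float = _CAL["tau_adapt"],
                       adapt_amplitude: float = _CAL["adapt_amplitude"]) -> NetworkParams:
    """Calibrated PPC-network parameters, rescaled to ``n_neurons``."""
    k = _scale(n_neurons)
    return NetworkParams(
        n_neurons=n_neurons,
        gain=_CAL["gain"],
        exc_amplitude=_CAL["exc_amplitude"] * k,
        inhibition=_CAL["inhibition"] * k,
        kernel_range=_CAL["kernel_range"],
        tau_input=_CAL["tau_ppc"],
        stim_halfwidth=_CAL["stim_halfwidth"],
        tau_adapt=tau_adapt,
        adapt_amplitude=adapt_amplitude,
    )


def validate_coupled(params_wm: NetworkParams, params_ppc: NetworkParams) -> None:
    """Check the structural constraints of a coupled WM+PPC configuration."""
    if params_wm.has_adaptation:
        raise ValueError("WM network must not carry adaptation")
    if not params_ppc.has_adaptation:
        raise ValueError("PPC network must carry adaptation parameters "
                         "(use adapt_amplitude=0 to disable its effect)")
    if not params_wm.tau_input < params_ppc.tau_input:
        raise ValueError("WM must integrate faster than PPC: tau_input(WM) < tau_input(PPC)")
    if params_wm.n_neurons != params_ppc.n_neurons:
        raise ValueError("coupled networks must have equal size")


@dataclass
class NetworkState:
    """Dynamical state of one network at a point in time."""

    input: np.ndarray        # h
    rate: np.ndarray         # r = logistic(gain * h)
    threshold: np.ndarray    # theta (zeros when adaptation absent)
    time: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.input.copy(), self.rate.copy(),
                            self.threshold.copy(), self.time)


def initial_state(params: NetworkParams) -> NetworkState:
    """Quiescent initial condition: strongly negative input, rate ~ 0."""
    h = np.full(params.n_neurons, params.h_init, dtype=float)
    r = 1.0 / (1.0 + np.exp(-params.gain * h))
    theta = np.zeros(params.n_neurons)
    return NetworkState(input=h, rate=r, threshold=theta, time=0.0)


# ---------------------------------------------------------------------------
# Config file round-trip


def _params_to_dict(p: NetworkParams) -> dict:
    d = {
        "n_neurons": p.n_neurons, "gain": p.gain,
        "exc_amplitude": p.exc_amplitude, "inhibition": p.inhibition,
        "kernel_range": p.kernel_range, "tau_input": p.tau_input,
        "stim_halfwidth": p.stim_halfwidth, "h_init": p.h_init,
    }
    if p.has_adaptation:
        d["tau_adapt"] = p.tau_adapt
        d["adapt_amplitude"] = p.adapt_amplitude
    return d


def dump_config(params_wm: NetworkParams, params_ppc: NetworkParams,
                dt: float = DEFAULT_DT) -> dict:
    """Serialize a coupled configuration to a plain dict (YAML-ready)."""
    return {
        "wm": _params_to_dict(params_wm),
        "ppc": _params_to_dict(params_ppc),
        "coupling": {"coupling_p_to_w": params_wm.coupling_p_to_w},
        "integration": {"dt": dt},
    }


def load_config(source) -> tuple[NetworkParams, NetworkParams, float]:
    """Load a coupled configuration from a YAML file path or mapping."""
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    wm = dict(cfg["wm"])
    wm["coupling_p_to_w"] = cfg.get("coupling", {}).get("coupling_p_to_w", 0.0)
    params_wm = NetworkParams(**wm)
    params_ppc = NetworkParams(**cfg["ppc"])
    validate_coupled(params_wm, params_ppc)
    dt = float(cfg.get("integration", {}).get("dt", DEFAULT_DT))
    return params_wm, params_ppc, dt


def with_adaptation(params_ppc: NetworkParams, tau_adapt=None,
                    adapt_amplitude=None) -> NetworkParams:
    """Return PPC params with overridden adaptation constants."""
    kw = {}
    if tau_adapt is not None:
        kw["tau_adapt"] = tau_adapt
    if adapt_amplitude is not None:
        kw["adapt_amplitude"] = adapt_amplitude
    return replace(params_ppc, **kw)
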