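"""Dynamics of the coupled line-attractor circuit.

The input ``h_i`` to neuron ``i`` relaxes with time constant ``tau``
toward the summed recurrent, coupling and external currents, and the
firing rate is the logistic readout ``r_i = 1 / (1 + exp(-beta h_i))``.
Recurrent weights are ``J_ij = (K_ij - J_0) / d_0`` with exponential
kernel ``K_ij = J_e exp(-|x_i - x_j| / d_0)``, zero self-coupling and
free (non-periodic) boundaries.  PPC neurons additionally carry an
adaptive threshold ``theta_i`` relaxing toward ``D * r_i`` with time
constant ``tau_theta``.

Integration is forward Euler.  Two equivalent evaluation paths exist for
the recurrent term: an explicit N x N matrix product (reference,
:func:`step_coupled`) and an O(N) two-pass recursion exploiting the
exponential kernel (:mod:`numba`-compiled, used by the session runner).
They agree to floating-point accuracy; a test asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .params import NetworkParams, NetworkState, initial_state

#: Sentinel returned when the rate profile has no discernible bump.
NO_BUMP = float("nan")


@dataclass(frozen=True)
class Connectivity:
    """Recurrent weight matrix and its excitatory kernel."""

    matrix: np.ndarray   # J_ij, zero diagonal, symmetric
    kernel: np.ndarray   # K_ij = J_e exp(-|x_i-x_j|/d_0)


def build_connectivity(params: NetworkParams) -> Connectivity:
    """Construct the exponential-kernel connectivity of one network."""
    x = params.firing_fields
    dist = np.abs(x[:, None] - x[None, :])
    kernel = params.exc_amplitude * np.exp(-dist / params.kernel_range)
    matrix = (kernel - params.inhibition) / params.kernel_range
    np.fill_diagonal(matrix, 0.0)
    return Connectivity(matrix=matrix, kernel=kernel)


def logistic_rate(h: np.ndarray, gain: float) -> np.ndarray:
    """Elementwise logistic transfer, strictly in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-gain * np.asarray(h, dtype=float)))


def stimulus_current(s: float, params: NetworkParams) -> np.ndarray:
    """Unit-amplitude box of half-width ``delta_s`` around stimulus ``s``.

    Neurons with firing field in the half-open window
    ``[s - delta_s, s + delta_s)`` receive input 1; the window is clipped
    at the attractor boundaries.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"stimulus {s} outside [0, 1]")
    n = params.n_neurons
    # index arithmetic keeps the neuron count deterministic at window
    # boundaries (i/n in [s - delta, s + delta) up to float rounding)
    lo = max(0, int(np.ceil((s - params.stim_halfwidth) * n - 1e-9)))
    hi = min(n, int(np.ceil((s + params.stim_halfwidth) * n - 1e-9)))
    out = np.zeros(n)
    out[lo:hi] = 1.0
    return out


def step_coupled(state_wm: NetworkState, state_ppc: NetworkState,
                 conn_wm: Connectivity, conn_ppc: Connectivity,
                 params_wm: NetworkParams, params_ppc: NetworkParams,
                 i_ext: np.ndarray, dt: float) -> tuple[NetworkState, NetworkState]:
    """One forward-Euler step of the coupled WM + PPC system.

    The external current drives both networks identically; the WM
    network additionally receives ``J_{P->W} r^P`` from the PPC, and the
    PPC input is reduced by its adaptive threshold.
    """
    n = params_wm.n_neurons
    i_ext = np.asarray(i_ext, dtype=float)
    if i_ext.shape != (n,) or state_ppc.input.shape != (n,):
        raise ValueError("vector length mismatch between networks and stimulus")

    drive_wm = conn_wm.matrix @ state_wm.rate \
        + params_wm.coupling_p_to_w * state_ppc.rate + i_ext
    drive_ppc = conn_ppc.matrix @ state_ppc.rate - state_ppc.threshold + i_ext

    h_wm = state_wm.input + (dt / params_wm.tau_input) * (-state_wm.input + drive_wm)
    h_ppc = state_ppc.input + (dt / params_ppc.tau_input) * (-state_ppc.input + drive_ppc)

    if params_ppc.has_adaptation:
        theta = state_ppc.threshold + (dt / params_ppc.tau_adapt) * (
            -state_ppc.threshold + params_ppc.adapt_amplitude * state_ppc.rate)
    else:
        theta = state_ppc.threshold.copy()

    t = state_wm.time + dt
    new_wm = NetworkState(h_wm, logistic_rate(h_wm, params_wm.gain),
                          state_wm.threshold.copy(), t)
    new_ppc = NetworkState(h_ppc, logistic_rate(h_ppc, params_ppc.gain), theta, t)
    return new_wm, new_ppc


def bump_location(rate: np.ndarray, flat_tol: float = 1e-3) -> tuple[float, float]:
    """Position and width of the activity bump.

    Returns ``(position, width)`` where position is ``argmax / N`` (ties
    broken toward the lowest index) and width is the full width at half
    height of the profile above its 10th-percentile baseline.  A profile
    whose max-min range falls below ``flat_tol`` has no bump and yields
    ``(NO_BUMP, NO_BUMP)`` (NaN sentinels) rather than a silent 0.
    """
    r = np.asarray(rate, dtype=float)
    if r.size == 0:
        raise ValueError("empty rate vector")
    baseline = np.percentile(r, 10.0)
    peak = r.max()
    if peak - r.min() < flat_tol:
        return NO_BUMP, NO_BUMP
    idx = int(np.argmax(r))
    half = baseline + 0.5 * (peak - baseline)
    above = r >= half
    lo = idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = idx
    while hi < r.size - 1 and above[hi + 1]:
        hi += 1
    width = (hi - lo + 1) / r.size
    return idx / r.size, width


def has_bump(position: float) -> bool:
    """True unless ``position`` is the no-bump sentinel."""
    return not np.isnan(position)


# ---------------------------------------------------------------------------
# Fast O(N) evolution used by the session runner


@njit(cache=True)
def _evolve(h_w, h_p, theta, stim, n_steps, dt,
            beta, je_w, j0_w, lam_w, d0_w, tau_w,
            je_p, j0_p, lam_p, d0_p, tau_p,
            tau_theta, d_adapt, j_pw):  # pragma: no cover - numba
    n = h_w.shape[0]
    r_w = np.empty(n)
    r_p = np.empty(n)
    f = np.empty(n)
    b = np.empty(n)
    rec_w = np.empty(n)
    rec_p = np.empty(n)
    for _ in range(n_steps):
        s_w = 0.0
        s_p = 0.0
        for i in range(n):
            r_w[i] = 1.0 / (1.0 + np.exp(-beta * h_w[i]))
            r_p[i] = 1.0 / (1.0 + np.exp(-beta * h_p[i]))
            s_w += r_w[i]
            s_p += r_p[i]
        # two-pass exponential convolution, WM network
        acc = 0.0
        for i in range(n):
            acc = r_w[i] + lam_w * acc
            f[i] = acc
        acc = 0.0
        for i in range(n - 1, -1, -1):
            acc = r_w[i] + lam_w * acc
            b[i] = acc
        for i in range(n):
            conv = je_w * (f[i] + b[i] - r_w[i])
            rec_w[i] = (conv - je_w * r_w[i] - j0_w * (s_w - r_w[i])) / d0_w
        # PPC network
        acc = 0.0
        for i in range(n):
            acc = r_p[i] + lam_p * acc
            f[i] = acc
        acc = 0.0
        for i in range(n - 1, -1, -1):
            acc = r_p[i] + lam_p * acc
            b[i] = acc
        for i in range(n):
            conv = je_p * (f[i] + b[i] - r_p[i])
            rec_p[i] = (conv - je_p * r_p[i] - j0_p * (s_p - r_p[i])) / d0_p
        for i in range(n):
            h_w[i] += (dt / tau_w) * (-h_w[i] + rec_w[i] + j_pw * r_p[i] + stim[i])
            h_p[i] += (dt / tau_p) * (-h_p[i] + rec_p[i] - theta[i] + stim[i])
            theta[i] += (dt / tau_theta) * (-theta[i] + d_adapt * r_p[i])


class CoupledCircuit:
    """Stateful fast simulator of the WM + PPC pair.

    Holds the mutable state vectors and advances them phase by phase
    (a phase = a span of constant external input).  The evolution is the
    same forward-Euler scheme as :func:`step_coupled`, evaluated with the
    O(N) exponential-kernel recursion.
    """

    def __init__(self, params_wm: NetworkParams, params_ppc: NetworkParams,
                 dt: float = 0.001):
        from .params import validate_coupled
        validate_coupled(params_wm, params_ppc)
        self.params_wm = params_wm
        self.params_ppc = params_ppc
        self.dt = float(dt)
        n = params_wm.n_neurons
        self._lam_w = np.exp(-1.0 / (n * params_wm.kernel_range))
        self._lam_p = np.exp(-1.0 / (n * params_ppc.kernel_range))
        st_w = initial_state(params_wm)
        st_p = initial_state(params_ppc)
        self.h_wm = st_w.input
        self.h_ppc = st_p.input
        self.theta = st_p.threshold
        self.time = 0.0
        self._zero = np.zeros(n)

    @property
    def rate_wm(self) -> np.ndarray:
        return logistic_rate(self.h_wm, self.params_wm.gain)

    @property
    def rate_ppc(self) -> np.ndarray:
        return logistic_rate(self.h_ppc, self.params_ppc.gain)

    def run(self, duration: float, stim: Optional[np.ndarray] = None) -> None:
        """Advance by ``duration`` seconds under a constant external input."""
        n_steps = int(round(duration / self.dt))
        if n_steps <= 0:
            return
        pw, pp = self.params_wm, self.params_ppc
        stim = self._zero if stim is None else np.asarray(stim, dtype=float)
        # adaptation disabled <=> D = 0 (theta relaxes to 0 over tau_theta)
        tau_theta = pp.tau_adapt if pp.has_adaptation else 1.0
        d_adapt = pp.adapt_amplitude if pp.has_adaptation else 0.0
        _evolve(self.h_wm, self.h_ppc, self.theta, stim, n_steps, self.dt,
                pw.gain, pw.exc_amplitude, pw.inhibition, self._lam_w,
                pw.kernel_range, pw.tau_input,
                pp.exc_amplitude, pp.inhibition, self._lam_p,
                pp.kernel_range, pp.tau_input,
                tau_theta, d_adapt, pw.coupling_p_to_w)
        self.time += n_steps * self.dt

    def present(self, s: float, duration: float = 0.4) -> None:
        """Present stimulus ``s`` as a unit box to both networks."""
        self.run(duration, stimulus_current(s, self.params_wm))

    def wm_bump(self) -> tuple[float, float]:
        return bump_location(self.rate_wm)

    def ppc_bump(self) -> tuple[float, float]:
        return bump_location(self.rate_ppc)


def steady_bump_width(params_wm: NetworkParams, params_ppc: NetworkParams,
                      dt: float = 0.001, settle: float = 2.0) -> float:
    """Width of the steady-state WM bump of a calibrated circuit.

    Used as the jump-detection scale: presents a central stimulus to a
    fresh circuit, lets it settle, and measures the FWHM.
    """
    circuit = CoupledCircuit(params_wm, params_ppc, dt=dt)
    circuit.present(0.5, 0.4)
    circuit.run(settle)
    _, width = circuit.wm_bump()
    if not has_bump(width):
        raise RuntimeError("calibrated circuit failed to form a bump")
    return width
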