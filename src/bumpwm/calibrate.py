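"""Calibration probes for the default network parameters.

The adaptation operating point is fixed by design
(``tau_adapt = 7.5 s``, ``adapt_amplitude = 0.3``: the drift regime) but
the remaining synaptic constants have to be found by search.  This
module contains the probes used to accept a candidate parameter set:

``wm_selfsustainment``
    An isolated WM network must hold a stimulus-evoked bump for >= 10 s
    with positional drift smaller than the bump width, and a single
    400 ms stimulus at a new location must displace the bump there.

``ppc_stimulus_resistance``
    An established PPC bump must *not* be displaced by a single 400 ms
    stimulus (the slow integration time filters brief inputs).

``ppc_regimes``
    At fixed ``tau_adapt = 7.5 s`` the PPC bump must be stable for small
    adaptation amplitude, drift (move while persisting) at D = 0.3, and
    dissipate quickly for large D.  The probe establishes a bump, lets
    the adaptive threshold build, displaces the bump off its adaptation
    field, and then tracks survival time and drift speed.

Run ``python -m bumpwm.calibrate`` to evaluate the shipped defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import CoupledCircuit, has_bump
from .params import NetworkParams, default_ppc_params, default_wm_params


@dataclass
class RegimeProbe:
    """Outcome of one adaptation-regime probe."""

    adapt_amplitude: float
    survival: float        # seconds until the bump peak collapses
    drift_path: float      # total |displacement| accumulated while alive
    drift_speed: float     # drift_path / survival

    @property
    def survived(self) -> bool:
        return self.survival >= 39.9


def wm_selfsustainment(params_wm: NetworkParams, params_ppc: NetworkParams,
                       dt: float = 0.001, hold: float = 10.0) -> dict:
    """Bump persistence and stimulus-following of the isolated WM network."""
    pw = replace(params_wm, coupling_p_to_w=0.0)
    c = CoupledCircuit(pw, params_ppc, dt=dt)
    c.run(1.0)
    baseline_peak = c.rate_wm.max()
    c.present(0.5, 0.4)
    c.run(hold)
    pos, width = c.wm_bump()
    peak = c.rate_wm.max()
    held = has_bump(pos) and peak > 0.8 and abs(pos - 0.5) < (width if has_bump(width) else 1.0)
    c.present(0.25, 0.4)
    c.run(0.3)
    pos2, _ = c.wm_bump()
    followed = has_bump(pos2) and abs(pos2 - 0.25) < 0.05
    return {"baseline_peak": float(baseline_peak), "held": bool(held),
            "position": float(pos), "width": float(width),
            "followed_new_stimulus": bool(followed)}


def ppc_stimulus_resistance(params_wm: NetworkParams, params_ppc: NetworkParams,
                            dt: float = 0.001) -> dict:
    """An established PPC bump should ignore one 400 ms stimulus."""
    c = CoupledCircuit(params_wm, params_ppc, dt=dt)
    c.run(1.0)
    c.present(0.5, 3.0)
    c.run(0.5)
    before, _ = c.ppc_bump()
    c.present(0.25, 0.4)
    c.run(0.3)
    after, _ = c.ppc_bump()
    resisted = has_bump(after) and abs(after - before) < 0.05
    return {"before": float(before), "after": float(after), "resisted": bool(resisted)}


def ppc_regime_probe(params_wm: NetworkParams, params_ppc: NetworkParams,
                     adapt_amplitude: float, dt: float = 0.001,
                     horizon: float = 40.0, shift_neurons: int = 8) -> RegimeProbe:
    """Track an established, displaced PPC bump under a given adaptation D."""
    pp = replace(params_ppc, adapt_amplitude=adapt_amplitude)
    c = CoupledCircuit(params_wm, pp, dt=dt)
    c.run(1.0)
    c.present(0.5, 3.0)   # establish (slow integration needs a long drive)
    c.run(2.0)            # let the adaptive threshold build
    c.h_ppc = np.roll(c.h_ppc, shift_neurons)
    survival, path, prev = horizon, 0.0, None
    step = 0.5
    for k in range(int(horizon / step)):
        c.run(step)
        pos, _ = c.ppc_bump()
        if not has_bump(pos) or c.rate_ppc.max() < 0.5:
            survival = (k + 1) * step
            break
        if prev is not None:
            path += abs(pos - prev)
        prev = pos
    return RegimeProbe(adapt_amplitude=adapt_amplitude, survival=survival,
                       drift_path=path, drift_speed=path / survival)


def check_defaults(n_neurons: int = 300, dt: float = 0.001,
                   d_stable: float = 0.05, d_drift: float = 0.3,
                   d_dissipate: float = 0.8) -> dict:
    """Evaluate all calibration conditions on the shipped defaults."""
    pw = default_wm_params(n_neurons)
    pp = default_ppc_params(n_neurons)
    out = {
        "wm": wm_selfsustainment(pw, pp, dt=dt),
        "ppc_resistance": ppc_stimulus_resistance(pw, pp, dt=dt),
        "regimes": {d: ppc_regime_probe(pw, pp, d, dt=dt)
                    for d in (d_stable, d_drift, d_dissipate)},
    }
    regs = out["regimes"]
    out["ok"] = (
        out["wm"]["held"] and out["wm"]["followed_new_stimulus"]
        and out["ppc_resistance"]["resisted"]
        and regs[d_stable].survival > regs[d_drift].survival > regs[d_dissipate].survival
        and regs[d_drift].drift_speed > regs[d_stable].drift_speed
    )
    return out


if __name__ == "__main__":
    result = check_defaults()
    print("WM:", result["wm"])
    print("PPC resistance:", result["ppc_resistance"])
    for d, probe in result["regimes"].items():
        print(f"D={d}: survival={probe.survival:.1f}s "
              f"path={probe.drift_path:.3f} speed={probe.drift_speed:.5f}/s")
    print("all conditions met:", result["ok"])
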