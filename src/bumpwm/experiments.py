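"""Named experiment presets and reproducibility plumbing.

A preset bundles a session configuration (or a sweep of them) with the
analysis stages to run on the result.  ``run_experiment`` executes
simulate -> analyze -> fit stages, writes every artifact under the
output directory and records an :class:`ExperimentManifest` so a run can
be reproduced and verified file-by-file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (bump_origin_fractions, contraction_bias_score,
                       history_bias_slope, performance_matrix,
                       psychometric_curve)
from .observers import empirical_accuracy_curves, fit_observer
from .glm import build_design, fit_bump_regression, fit_choice_glm
from .params import default_ppc_params, default_wm_params
from .task import SessionConfig, run_session, save_trials

#: Scaled-down defaults: network size and trial counts chosen so a preset
#: completes in minutes on one core while keeping every effect measurable.
DEFAULT_N = 300
DEFAULT_DT = 0.002
DEFAULT_TRIALS = 200
FULL_TRIALS = 1000


@dataclass
class ExperimentManifest:
    """Record of one experiment run."""

    name: str
    seed: int
    version: str
    config: dict
    outputs: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _simulate(config: SessionConfig, n_neurons: int, dt: float) -> pd.DataFrame:
    pw = default_wm_params(n_neurons)
    pp = default_ppc_params(n_neurons)
    return run_session(config, pw, pp, dt=dt)


def _analyze(df: pd.DataFrame, outdir: Path, tag: str,
             manifest: ExperimentManifest) -> dict:
    dist_mean = 0.5
    perf = performance_matrix(df)
    perf.to_csv(outdir / f"performance_matrix_{tag}.csv")
    manifest.outputs[f"performance_matrix_{tag}"] = str(outdir / f"performance_matrix_{tag}.csv")
    summary = {"accuracy": float(df["correct"].mean())}
    try:
        psy = psychometric_curve(df)
        psy.to_csv(outdir / f"psychometric_{tag}.csv", index=False)
        manifest.outputs[f"psychometric_{tag}"] = str(outdir / f"psychometric_{tag}.csv")
        summary["psychometric_accuracy"] = float(
            df[df.is_psychometric]["correct"].mean())
    except ValueError:
        pass
    bias = history_bias_slope(df, 1)
    summary["one_back_slope"] = bias.pooled_slope
    summary["one_back_ci"] = [bias.ci_low, bias.ci_high]
    bp, bm = contraction_bias_score(df, dist_mean)
    summary["bias_plus"], summary["bias_minus"] = bp, bm
    summary["jump_fraction"] = float(df["ppc_jump_prev"].mean())
    return summary


PRESETS: dict[str, dict] = {
    "interleaved_default": {"kw": {}},
    "block_design": {"kw": {"design": "block", "delays": (6.0,)}},
    "ppc_inactivation": {"kw": {"ppc_coupling_scale": 0.0}},
    "no_adaptation": {"kw": {"adaptation_on": False}},
    "iti_sweep": {"sweep": [("iti_2.2", {"iti": 2.2}), ("iti_6", {"iti": 6.0}),
                            ("iti_11", {"iti": 11.0})]},
    "adaptation_sweep": {"sweep": [("tau_short", {"tau_adapt_override": 2.5}),
                                   ("tau_default", {}),
                                   ("tau_long", {"tau_adapt_override": 20.0})]},
    "observer_comparison": {"kw": {}, "fit_observers": True},
}


def run_experiment(name: str, outdir, seed: int = 0,
                   n_trials: int = DEFAULT_TRIALS,
                   n_neurons: int = DEFAULT_N, dt: float = DEFAULT_DT,
                   full: bool = False) -> ExperimentManifest:
    """Execute a named preset end to end and write its manifest."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    preset = PRESETS[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if full:
        n_trials = FULL_TRIALS
    t0 = time.time()
    manifest = ExperimentManifest(
        name=name, seed=seed, version=__version__,
        config={"n_trials": n_trials, "n_neurons": n_neurons, "dt": dt,
                "preset": preset.get("kw", {})})

    runs = preset.get("sweep", [("main", preset.get("kw", {}))])
    summaries = {}
    for tag, kw in runs:
        cfg = SessionConfig(n_trials=n_trials, seed=seed, **kw)
        df = _simulate(cfg, n_neurons, dt)
        path = outdir / f"session_{tag}.csv"
        save_trials(df, path)
        manifest.outputs[f"session_{tag}"] = str(path)
        manifest.stages_completed.append(f"simulate:{tag}")
        summaries[tag] = _analyze(df, outdir, tag, manifest)
        manifest.stages_completed.append(f"analyze:{tag}")
        if preset.get("fit_observers"):
            from .stimdist import make_distribution
            curves = empirical_accuracy_curves(df)
            dist = cfg.distribution
            fits = {m: fit_observer(curves, m, dist) for m in ("stat", "bayes")}
            summaries[tag]["observer_fits"] = {
                m: {"params": f.params, "mse": f.loss} for m, f in fits.items()}
            manifest.stages_completed.append(f"fit-observers:{tag}")
        try:
            y, X = build_design(df, h=4)
            fit = fit_choice_glm(y, X)
            summaries[tag]["glm"] = {
                "alpha": fit.alpha, "history_weights": list(fit.history_weights),
                "mean_weight": fit.mean_weight, "gamma": fit.gamma}
            manifest.stages_completed.append(f"glm:{tag}")
        except Exception as exc:   # partial failure: recorded, not fatal
            summaries[tag]["glm_error"] = str(exc)

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2, default=float))
    manifest.outputs["summary"] = str(summary_path)
    manifest.wall_clock_s = time.time() - t0
    manifest.outputs = {k: {"path": v, "sha256": file_hash(v)}
                        for k, v in manifest.outputs.items()}
    manifest.save(outdir / "manifest.json")
    return manifest
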