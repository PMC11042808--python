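"""Shared fixtures.

The circuit simulations are the expensive part of the suite, so sessions
are simulated once per test run in session-scoped fixtures and shared
between the behavioral tests.  All simulations use the calibrated
defaults at N = 300 with dt = 2 ms (the coarse step passes the
convergence check exercised in test_network).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bumpwm.params import default_ppc_params, default_wm_params
from bumpwm.stimdist import make_distribution
from bumpwm.task import SessionConfig, run_session

N_NEURONS = 300
DT = 0.002


def simulate_sessions(seeds, n_trials, **config_kw) -> pd.DataFrame:
    pw = default_wm_params(N_NEURONS)
    pp = default_ppc_params(N_NEURONS)
    frames = []
    for seed in seeds:
        cfg = SessionConfig(n_trials=n_trials, seed=seed, **config_kw)
        df = run_session(cfg, pw, pp, dt=DT)
        df["session"] = seed
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def intact_sessions() -> pd.DataFrame:
    """Five seeds of the default interleaved protocol (delays 2/6/10 s)."""
    return simulate_sessions(seeds=(1, 2, 3, 4, 5), n_trials=250)


@pytest.fixture(scope="session")
def inactivated_sessions() -> pd.DataFrame:
    """PPC-to-WM coupling removed, matched seeds."""
    return simulate_sessions(seeds=(1, 2, 3), n_trials=150,
                             ppc_coupling_scale=0.0)


@pytest.fixture(scope="session")
def no_adaptation_sessions() -> pd.DataFrame:
    """Adaptation knocked out (D = 0), matched seeds."""
    return simulate_sessions(seeds=(1, 2, 3), n_trials=200,
                             adaptation_on=False)


@pytest.fixture(scope="session")
def iti_sessions() -> dict:
    """Sessions at three inter-trial intervals.  The longest ITI gets
    twelve seeds because the lag >= 3 sign pattern tested there is the
    most statistics-hungry quantity in the suite."""
    return {2.2: simulate_sessions(seeds=(1, 2, 3, 4, 5, 6), n_trials=120,
                                   iti=2.2),
            6.0: simulate_sessions(seeds=(1, 2, 3, 4, 5, 6), n_trials=120,
                                   iti=6.0),
            11.0: simulate_sessions(seeds=tuple(range(1, 13)), n_trials=120,
                                    iti=11.0)}


@pytest.fixture(scope="session")
def uniform10():
    return make_distribution("uniform", support=np.linspace(0.05, 0.95, 10))


@pytest.fixture(scope="session")
def task_distribution():
    return SessionConfig().distribution
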