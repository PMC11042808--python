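"""Unit tests of the rate-network core: connectivity, transfer function,
stimulus windows, Euler stepping, bump readout, and the equivalence of the
matrix and fast evaluation paths."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as hst

from bumpwm.network import (CoupledCircuit, NO_BUMP, build_connectivity,
                            bump_location, has_bump, logistic_rate,
                            step_coupled, stimulus_current)
from bumpwm.params import (NetworkParams, default_ppc_params,
                           default_wm_params, initial_state, load_config,
                           dump_config, validate_coupled)


def small_params(n=100, **kw):
    base = dict(n_neurons=n, gain=2.0, exc_amplitude=0.01, inhibition=0.003,
                kernel_range=0.05, tau_input=0.05, stim_halfwidth=0.05)
    base.update(kw)
    return NetworkParams(**base)


class TestConnectivity:
    def test_kernel_at_one_range_distance(self):
        # two neurons one kernel-range apart: K = J_e / e
        p = small_params(n=100, kernel_range=0.1)
        conn = build_connectivity(p)
        i, j = 0, 10   # |x_i - x_j| = 0.1 = d_0
        assert conn.kernel[i, j] == pytest.approx(p.exc_amplitude * np.exp(-1.0))

    def test_symmetric_zero_diagonal(self):
        conn = build_connectivity(small_params())
        assert np.array_equal(conn.matrix, conn.matrix.T)
        assert np.all(np.diag(conn.matrix) == 0.0)

    def test_kernel_sum_invariant_under_range(self):
        # the d0 rescaling keeps the summed kernel constant: exactly so
        # for interior rows, and for the full sum up to the boundary
        # share (direct summation puts that share at ~5% here)
        totals, interiors = [], []
        for d0 in (0.05, 0.10):
            p = small_params(n=200, exc_amplitude=1.0, kernel_range=d0)
            conn = build_connectivity(p)
            totals.append(conn.kernel.sum() / d0)
            interiors.append(conn.kernel[100].sum() / d0)
        assert abs(interiors[0] - interiors[1]) / interiors[0] < 0.01
        assert abs(totals[0] - totals[1]) / totals[0] < 0.06

    def test_invalid_params_refused(self):
        with pytest.raises(ValueError):
            small_params(n=1)
        with pytest.raises(ValueError):
            small_params(kernel_range=0.0)


class TestLogisticRate:
    def test_midpoint_and_closed_form(self):
        assert logistic_rate(np.array([0.0]), 3.7)[0] == pytest.approx(0.5)
        assert logistic_rate(np.array([np.log(3.0)]), 1.0)[0] == pytest.approx(0.75)

    def test_monotone_in_gain_for_positive_input(self):
        h = np.array([0.7])
        rates = [logistic_rate(h, b)[0] for b in (1.0, 2.0, 5.0, 10.0)]
        assert np.all(np.diff(rates) > 0)
        assert rates[-1] < 1.0

    @given(hst.floats(-4, 4), hst.floats(0.1, 8))
    @settings(max_examples=50, deadline=None)
    def test_open_unit_interval(self, h, gain):
        # strict (0, 1) over the operating range of beta * h (float64
        # saturates only beyond |beta * h| ~ 37)
        r = logistic_rate(np.array([h]), gain)[0]
        assert 0.0 < r < 1.0


class TestStimulusCurrent:
    def test_central_window_exact_neurons(self):
        p = small_params(n=100, stim_halfwidth=0.05)
        cur = stimulus_current(0.5, p)
        active = np.flatnonzero(cur)
        assert list(active) == list(range(45, 55))
        assert set(np.unique(cur)) <= {0.0, 1.0}

    def test_left_clipped_window(self):
        p = small_params(n=100, stim_halfwidth=0.05)
        assert stimulus_current(0.0, p).sum() == 5

    @given(hst.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_window_size_bound(self, s):
        p = small_params(n=100, stim_halfwidth=0.05)
        assert stimulus_current(s, p).sum() <= np.ceil(2 * 0.05 * 100)

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            stimulus_current(1.5, small_params())


class TestStepCoupled:
    def _states(self, pw, pp):
        return initial_state(pw), initial_state(pp)

    def test_single_neuron_euler_update(self):
        # no recurrence (J_e = J_0 = 0): one step is plain Euler relaxation
        pw = small_params(n=2, exc_amplitude=0.0, inhibition=0.0)
        pp = small_params(n=2, exc_amplitude=0.0, inhibition=0.0,
                          tau_adapt=1.0, adapt_amplitude=0.0)
        sw, sp = self._states(pw, pp)
        h0 = sw.input[0]
        i_ext = np.array([2.0, 0.0])
        dt = 0.001
        new_w, _ = step_coupled(sw, sp, build_connectivity(pw),
                                build_connectivity(pp), pw, pp, i_ext, dt)
        # h(dt) = h0 + dt/tau (-h0 + I + J_pw * r_p)
        expected = h0 + dt / pw.tau_input * (
            -h0 + 2.0 + pw.coupling_p_to_w * sp.rate[0])
        assert new_w.input[0] == pytest.approx(expected, rel=1e-12)

    def test_threshold_fixed_point(self):
        # clamp r_p at c: theta -> D * c within 1% after 5 tau_theta
        pp = small_params(n=4, tau_adapt=0.5, adapt_amplitude=0.4)
        theta = np.zeros(4)
        c = 0.7
        dt, tau = 0.001, 0.5
        for _ in range(int(5 * tau / dt)):
            theta += (dt / tau) * (-theta + 0.4 * c)
        assert np.allclose(theta, 0.4 * c, rtol=0.01)

    def test_decoupling_matches_isolated_run(self):
        pw = small_params(coupling_p_to_w=0.0)
        pp = small_params(tau_input=0.5, tau_adapt=2.0, adapt_amplitude=0.2)
        c1 = CoupledCircuit(pw, pp, dt=0.001)
        c1.run(0.5, stimulus_current(0.5, pw))
        # the same WM with an arbitrary different PPC state must agree
        c2 = CoupledCircuit(pw, pp, dt=0.001)
        c2.h_ppc += 1.3
        c2.run(0.5, stimulus_current(0.5, pw))
        assert np.allclose(c1.h_wm, c2.h_wm)

    def test_shape_mismatch(self):
        pw, pp = small_params(n=10), small_params(
            n=10, tau_input=0.5, tau_adapt=1.0, adapt_amplitude=0.1)
        sw, sp = self._states(pw, pp)
        with pytest.raises(ValueError):
            step_coupled(sw, sp, build_connectivity(pw), build_connectivity(pp),
                         pw, pp, np.zeros(7), 0.001)


class TestFastPathEquivalence:
    def test_fast_evolution_matches_matrix_step(self):
        """The O(N) recursion and the N x N matrix product implement the
        same dynamics to floating-point accuracy."""
        pw = default_wm_params(120)
        pp = default_ppc_params(120)
        conn_w, conn_p = build_connectivity(pw), build_connectivity(pp)
        sw, sp = initial_state(pw), initial_state(pp)
        stim = stimulus_current(0.4, pw)
        circuit = CoupledCircuit(pw, pp, dt=0.001)
        n_steps = 200
        for _ in range(n_steps):
            sw, sp = step_coupled(sw, sp, conn_w, conn_p, pw, pp, stim, 0.001)
        circuit.run(n_steps * 0.001, stim)
        assert np.allclose(circuit.h_wm, sw.input, atol=1e-9)
        assert np.allclose(circuit.h_ppc, sp.input, atol=1e-9)
        assert np.allclose(circuit.theta, sp.threshold, atol=1e-9)

    def test_determinism(self):
        runs = []
        for _ in range(2):
            c = CoupledCircuit(default_wm_params(100), default_ppc_params(100),
                               dt=0.002)
            c.run(0.5)
            c.present(0.3, 0.4)
            c.run(1.0)
            runs.append(c.h_wm.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_rate_boundedness(self):
        c = CoupledCircuit(default_wm_params(100), default_ppc_params(100),
                           dt=0.002)
        c.present(0.5, 0.4)
        for _ in range(5):
            c.run(1.0)
            for r in (c.rate_wm, c.rate_ppc):
                assert np.all(r > 0.0) and np.all(r < 1.0)


class TestBumpLocation:
    def test_unique_max_position(self):
        r = np.full(100, 0.05)
        r[40:46] = [0.2, 0.6, 0.9, 0.8, 0.5, 0.2]
        pos, width = bump_location(r)
        assert pos == pytest.approx(0.42)
        assert 0 < width < 0.2

    def test_flat_profile_flagged(self):
        pos, width = bump_location(np.full(50, 0.3))
        assert not has_bump(pos) and not has_bump(width)

    def test_tie_broken_to_lowest_index(self):
        r = np.zeros(10)
        r[[3, 7]] = 1.0
        pos, _ = bump_location(r)
        assert pos == pytest.approx(0.3)

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            bump_location(np.array([]))

    def test_isolated_wm_keeps_stimulus_location(self):
        pw = replace(default_wm_params(200), coupling_p_to_w=0.0)
        pp = default_ppc_params(200)
        c = CoupledCircuit(pw, pp, dt=0.001)
        c.run(0.5)
        c.present(0.5, 0.4)
        c.run(1.0)
        pos, width = c.wm_bump()
        assert has_bump(pos)
        assert abs(pos - 0.5) < pw.stim_halfwidth + width


class TestParamsAndConfig:
    def test_coupled_constraints(self):
        pw = default_wm_params(100)
        pp = default_ppc_params(100)
        validate_coupled(pw, pp)   # no raise
        with pytest.raises(ValueError):
            validate_coupled(pp, pp)
        slow_wm = replace(pw, tau_input=pp.tau_input + 1.0)
        with pytest.raises(ValueError):
            validate_coupled(slow_wm, pp)

    def test_adaptation_fields_together(self):
        with pytest.raises(ValueError):
            small_params(tau_adapt=1.0)

    def test_config_roundtrip(self, tmp_path):
        import yaml
        pw, pp = default_wm_params(80), default_ppc_params(80)
        cfg = dump_config(pw, pp, dt=0.002)
        path = tmp_path / "net.yaml"
        path.write_text(yaml.safe_dump(cfg))
        pw2, pp2, dt = load_config(path)
        assert pw2 == pw and pp2 == pp and dt == 0.002


def test_coarse_step_convergence():
    """Bump position at dt = 2 ms agrees with dt = 1 ms to within a tenth
    of the bump width (the condition for using the coarse step in the
    scaled-down session tests)."""
    positions = {}
    for dt in (0.002, 0.001):
        c = CoupledCircuit(default_wm_params(300), default_ppc_params(300), dt=dt)
        c.run(1.0)
        c.present(0.5, 0.4)
        c.run(5.0)
        positions[dt], width = c.wm_bump()
    assert abs(positions[0.002] - positions[0.001]) < width / 10
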