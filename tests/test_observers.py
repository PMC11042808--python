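"""Observer models: replacement-error arithmetic against an enumeration
oracle, the Bayesian observer against a Monte-Carlo oracle, structural
properties of the performance curves, and parameter-recovery fits."""

import numpy as np
import pandas as pd
import pytest

from bumpwm.observers import (BayesObserver, StatObserver, bayes_response_prob,
                              bayes_response_prob_quadrature,
                              empirical_accuracy_curves, error_probability,
                              fit_observer, predict_performance_curves,
                              replacement_error_core)
from bumpwm.stimdist import make_distribution
from bumpwm.synth import GeneratorSpec, sample_session


def enumerate_error(s1, s2, dist):
    """Oracle: enumerate every replacement value and its outcome."""
    p = 0.0
    for s_hat, prob in zip(dist.support, dist.probs):
        if s_hat == s2:
            p += prob * 0.5            # tie: fair coin
        elif (s1 > s2 and s_hat < s2) or (s1 < s2 and s_hat > s2):
            p += prob
    return p


DISTS = ["uniform", "neg_skewed", "bimodal"]


class TestReplacementModel:
    @pytest.mark.parametrize("label", DISTS)
    def test_matches_enumeration_exactly(self, label):
        dist = make_distribution(label, support=np.linspace(0.05, 0.95, 10))
        obs = StatObserver(epsilon=0.73, replacement_dist=dist)
        for s1 in dist.support:
            for s2 in dist.support:
                if s1 == s2:
                    continue
                expect = 0.73 * enumerate_error(s1, s2, dist)
                assert error_probability(s1, s2, obs) == pytest.approx(
                    expect, abs=1e-12)

    def test_zero_epsilon_means_no_errors(self, uniform10):
        obs = StatObserver(epsilon=0.0, replacement_dist=uniform10)
        assert error_probability(uniform10.support[0], uniform10.support[5],
                                 obs) == 0.0

    def test_uniform_closed_form(self, uniform10):
        # third-smallest s2, s1 above: eps * (pm/2 + mass below) = 0.25
        obs = StatObserver(epsilon=1.0, replacement_dist=uniform10)
        s2 = uniform10.support[2]
        assert error_probability(uniform10.support[7], s2, obs) == \
            pytest.approx(0.25)

    def test_error_depends_on_s1_only_through_side(self, uniform10):
        obs = StatObserver(epsilon=0.5, replacement_dist=uniform10)
        s2 = uniform10.support[4]
        above = {error_probability(s1, s2, obs)
                 for s1 in uniform10.support if s1 > s2}
        assert len(above) == 1

    def test_off_support_s2_on_uniform_grid_has_no_tie_mass(self, uniform10):
        obs = StatObserver(epsilon=1.0, replacement_dist=uniform10)
        # s2 = 0.5 sits between grid points 0.45 and 0.55: below-mass 0.5
        assert error_probability(0.9, 0.5, obs) == pytest.approx(0.5)

    def test_off_support_s2_nonuniform_grid_refused(self):
        from bumpwm.stimdist import StimulusDistribution
        dist = StimulusDistribution(np.array([0.1, 0.2, 0.5, 0.9]),
                                    np.full(4, 0.25))
        obs = StatObserver(epsilon=0.5, replacement_dist=dist)
        with pytest.raises(ValueError):
            error_probability(0.9, 0.3, obs)

    def test_lapse_floor(self, uniform10):
        obs = StatObserver(epsilon=0.5, lapse=1.0, replacement_dist=uniform10)
        s = uniform10.support
        assert error_probability(s[6], s[2], obs) == pytest.approx(0.5)

    @pytest.mark.parametrize("label", DISTS)
    def test_accuracy_monotone_per_side(self, label):
        dist = make_distribution(label, support=np.linspace(0.05, 0.95, 12))
        obs = StatObserver(epsilon=1.0, replacement_dist=dist)
        step = dist.support[1] - dist.support[0]
        pairs = [(s1, s1 - step) for s1 in dist.support[1:]] + \
                [(s1, s1 + step) for s1 in dist.support[:-1]]
        curves = predict_performance_curves(pairs, obs)
        below = curves[curves.side == "s1>s2"].sort_values("s1")["accuracy"]
        above = curves[curves.side == "s1<s2"].sort_values("s1")["accuracy"]
        assert np.all(np.diff(below) <= 1e-12)
        assert np.all(np.diff(above) >= -1e-12)


def crossing_point(curves):
    """Interpolated s1 where the two diagonal sides perform equally."""
    piv = curves.pivot_table(index="s1", columns="side", values="accuracy")
    piv = piv.dropna()
    gap = piv["s1>s2"] - piv["s1<s2"]
    sign_change = np.flatnonzero(np.diff(np.sign(gap)) != 0)
    if len(sign_change) == 0:
        return np.nan
    i = sign_change[0]
    x0, x1 = piv.index[i], piv.index[i + 1]
    g0, g1 = gap.iloc[i], gap.iloc[i + 1]
    return x0 - g0 * (x1 - x0) / (g1 - g0)


class TestCurveCrossings:
    def _curves(self, dist, observer):
        step = dist.support[1] - dist.support[0]
        pairs = [(s1, s1 - step) for s1 in dist.support[1:]] + \
                [(s1, s1 + step) for s1 in dist.support[:-1]]
        return predict_performance_curves(pairs, observer)

    def test_symmetric_crossing_at_mean(self):
        dist = make_distribution("symmetric", support=np.linspace(0.1, 0.9, 9))
        obs = StatObserver(epsilon=1.0, replacement_dist=dist)
        cross = crossing_point(self._curves(dist, obs))
        assert cross == pytest.approx(dist.mean, abs=0.05)

    def test_neg_skewed_crossing_at_median_right_of_mean(self):
        dist = make_distribution("neg_skewed",
                                 support=np.linspace(0.1, 0.9, 9), skew=3.0)
        obs = StatObserver(epsilon=1.0, replacement_dist=dist)
        cross = crossing_point(self._curves(dist, obs))
        step = dist.support[1] - dist.support[0]
        assert abs(cross - dist.median) <= step
        assert cross > dist.mean

    def test_bayes_nonmonotone_for_bimodal_prior(self):
        # matched parameters: sigma = 0.12 against epsilon = 0.5
        dist = make_distribution("bimodal", support=np.linspace(0.1, 0.9, 9))
        bayes = BayesObserver(sigma1=0.12, prior=dist)
        curves = self._curves(dist, bayes)
        below = curves[curves.side == "s1>s2"].sort_values("s1")["accuracy"]
        above = curves[curves.side == "s1<s2"].sort_values("s1")["accuracy"]
        monotone_b = np.all(np.diff(below) <= 1e-9)
        monotone_a = np.all(np.diff(above) >= -1e-9)
        assert not (monotone_b and monotone_a)


class TestBayesObserver:
    def mc_oracle(self, s1, s2, obs, n=200_000, seed=0):
        rng = np.random.default_rng(seed)
        prior = obs.prior
        r1 = rng.normal(s1, obs.sigma1, n)
        z2 = ((prior.support[None, :] - r1[:, None]) / obs.sigma1) ** 2
        w = prior.probs[None, :] * np.exp(-0.5 * (z2 - z2.min(1, keepdims=True)))
        tot = w.sum(1)
        below = w[:, prior.support < s2].sum(1)
        at = w[:, np.isclose(prior.support, s2)].sum(1)
        y = (below + 0.5 * at) / tot > 0.5
        p = y.mean()
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        return p, se

    @pytest.mark.parametrize("label,s1,s2,sigma", [
        ("uniform", 0.35, 0.45, 0.12),
        ("uniform", 0.65, 0.45, 0.30),
        ("neg_skewed", 0.25, 0.45, 0.08),
        ("bimodal", 0.55, 0.35, 0.20),
    ])
    def test_matches_monte_carlo(self, label, s1, s2, sigma):
        dist = make_distribution(label, support=np.linspace(0.05, 0.95, 10))
        obs = BayesObserver(sigma1=sigma, prior=dist)
        exact = bayes_response_prob(s1, s2, obs)
        mc, se = self.mc_oracle(s1, s2, obs)
        assert abs(exact - mc) < 3 * se + 1e-4

    def test_degenerate_likelihood_is_step(self, uniform10):
        obs = BayesObserver(sigma1=1e-6, prior=uniform10)
        assert bayes_response_prob(0.35, 0.45, obs) == pytest.approx(1.0)
        assert bayes_response_prob(0.55, 0.45, obs) == pytest.approx(0.0)

    def test_symmetric_prior_midpoint(self):
        dist = make_distribution("symmetric", support=np.linspace(0.1, 0.9, 9))
        obs = BayesObserver(sigma1=0.2, prior=dist)
        assert bayes_response_prob(0.5, 0.5, obs) == pytest.approx(0.5, abs=1e-6)

    def test_quadrature_crosscheck(self, uniform10):
        obs = BayesObserver(sigma1=0.15, prior=uniform10)
        exact = bayes_response_prob(0.35, 0.55, obs)
        quad = bayes_response_prob_quadrature(0.35, 0.55, obs)
        assert abs(exact - quad) < 2e-3


class TestObserverFits:
    def _model_curves(self, dist, eps, lapse=0.0):
        obs = StatObserver(epsilon=eps, lapse=lapse, replacement_dist=dist)
        step = dist.support[1] - dist.support[0]
        pairs = [(s1, s1 - step) for s1 in dist.support[1:]] + \
                [(s1, s1 + step) for s1 in dist.support[:-1]]
        return predict_performance_curves(pairs, obs)

    def test_epsilon_selfconsistency(self, uniform10):
        curves = self._model_curves(uniform10, eps=0.5)
        fit = fit_observer(curves, "stat", uniform10)
        assert fit.params["epsilon"] == pytest.approx(0.5, abs=1e-6)
        assert fit.loss < 1e-14

    def test_sigma_selfconsistency(self, uniform10):
        obs = BayesObserver(sigma1=0.2, prior=uniform10)
        step = uniform10.support[1] - uniform10.support[0]
        pairs = [(s1, s1 - step) for s1 in uniform10.support[1:]] + \
                [(s1, s1 + step) for s1 in uniform10.support[:-1]]
        curves = predict_performance_curves(pairs, obs)
        fit = fit_observer(curves, "bayes", uniform10)
        assert fit.params["sigma"] == pytest.approx(0.2, rel=0.1)

    def test_lapse_recovery(self, uniform10):
        curves = self._model_curves(uniform10, eps=0.5, lapse=0.1)
        fit = fit_observer(curves, "stat", uniform10, fit_lapse=True)
        assert fit.params["lapse"] == pytest.approx(0.1, abs=0.02)
        assert fit.params["epsilon"] == pytest.approx(0.5, abs=0.05)

    def test_flat_curves_flagged(self, uniform10):
        # same s2, same diagonal side: the replacement mass is identical
        # for both pairs, so epsilon cannot be identified
        curves = pd.DataFrame({"s1": [0.65, 0.75], "s2": [0.55, 0.55],
                               "accuracy": [0.8, 0.8]})
        fit = fit_observer(curves, "stat", uniform10)
        assert fit.non_identifiable

    def test_synthetic_trials_recover_epsilon(self):
        dist = make_distribution("uniform", support=np.linspace(0.15, 0.85, 8))
        spec = GeneratorSpec(distribution=dist, n_trials=10_000,
                             epsilon_base=0.5, seed=3)
        trials = sample_session(spec)
        curves = empirical_accuracy_curves(trials)
        fit = fit_observer(curves, "stat", dist)
        assert fit.params["epsilon"] == pytest.approx(0.5, abs=0.05)
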