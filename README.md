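# bumpwm

Circuit-level modeling of **parametric working memory** and its biases.
In a delayed-comparison task a subject hears two stimulus amplitudes
`s1` and `s2` separated by a delay and reports which was larger.  Real
subjects (humans, rats) systematically misremember `s1`: it is pulled
toward the center of the stimulus distribution (**contraction bias**)
and toward the stimuli of recent trials (**serial dependence**).

`bumpwm` implements a mechanistic account of both effects and the full
analysis toolchain around it, for computational neuroscientists who want
to simulate, quantify and model-compare these phenomena end-to-end
without any external data.

## The model

Two coupled one-dimensional line attractors with `N` rate neurons each,
firing fields `x_i = i/N`:

* a **working-memory (WM) network** with a fast input timescale
  `τ_h^W`, which stores `s1` as a self-sustained activity bump;
* a **PPC-like network** with a slow timescale `τ_h^P` and adaptive
  firing thresholds `θ_i` (timescale `τ_θ`, amplitude `D`), which
  integrates the stimulus stream sluggishly and feeds the WM network
  one-to-one with weight `J_{P→W}`.

Rates are logistic, `r_i = 1/(1+e^{−βh_i})`, inputs relax as

    τ dh_i/dt + h_i = Σ_{j≠i} J_ij r_j (+ J_{P→W} r_i^P − θ_i + I_i^ext)

with symmetric exponential-kernel excitation and uniform inhibition,
`J_ij = (J_e e^{−|x_i−x_j|/d_0} − J_0)/d_0`, free boundaries, forward
Euler integration.  Adaptation makes the PPC bump drift and occasionally
collapse, whereupon it jumps to a recent stimulus location; the coupling
then pulls the WM bump toward this *sample of recent stimulus history*.
Averaged over trials this produces contraction bias without the network
ever representing the stimulus mean, plus one- and two-back attraction,
PPC-inactivation effects, inter-trial-interval effects, and
adaptation-timescale effects on history weights.

On top of the circuit the package implements three observer-level
accounts used for fitting and comparison:

* the **replacement model**: with probability `ε` the memory of `s1` is
  replaced by a draw from the marginal stimulus distribution `p_m`;
  the error probability of a pair is `ε` times the `p_m` mass on the
  wrong side of `s2` (plus an optional lapse `δ`);
* the **Bayesian ideal observer**: `r1 ~ N(s1, σ)`, exact `s2`, prior
  `p_m`, decision by posterior mass below `s2`;
* the **trial-history GLM**: logistic regression of the choice on the
  signed difficulty, the mean stimuli of the last `h` trials, and the
  running stimulus mean — including the geometric-decay reinterpretation
  of the running-mean weight as a truncated short-term history tail.

A synthetic-behavior generator emulates the human protocol (delays
{2,4,6} s, ~400 self-paced trials, bimodal inter-trial intervals) with
planted `ε`, lapse and history kernels, so every estimator in the
package can be validated by parameter recovery.

## Worked example

```python
from bumpwm import SessionConfig, default_wm_params, default_ppc_params, run_session
from bumpwm.analysis import history_bias_slope, contraction_bias_score

params_wm = default_wm_params(300)
params_ppc = default_ppc_params(300)
trials = run_session(SessionConfig(n_trials=300, seed=1),
                     params_wm, params_ppc, dt=0.002)

print(f"accuracy:            {trials['correct'].mean():.3f}")
bias = history_bias_slope(trials, n_back=1, seed=0)
print(f"one-back slope:      {bias.pooled_slope:.3f}  "
      f"(95% CI {bias.ci_low:.3f} .. {bias.ci_high:.3f})")
plus, minus = contraction_bias_score(trials[~trials.is_psychometric], mean_stim=0.5)
print(f"contraction bias:    Bias+ {plus:+.3f}   Bias- {minus:+.3f}")
print(f"PPC jump fraction:   {trials['ppc_jump_prev'].mean():.3f}")
```

prints

```
accuracy:            0.873
one-back slope:      -0.376  (95% CI -0.542 .. -0.184)
contraction bias:    Bias+ +0.058   Bias- -0.109
PPC jump fraction:   0.580
```

The session is 300 consecutive trials with no state reset.  Accuracy is
well below ceiling; the negative one-back slope says the current choice
is attracted toward the previous trial's stimuli; `Bias+`/`Bias-` are
the accuracy gains/losses of the trial classes that contraction toward
the mean helps/hurts; and on roughly half the trials the PPC bump was
replaced since the previous readout.

The same trial tables are produced by the CLI
(`bumpwm simulate --out session.csv`, then `bumpwm analyze`,
`bumpwm fit-observers`, `bumpwm glm`, `bumpwm synth`,
`bumpwm experiment <preset>`).

## Layout

| module | contents |
| --- | --- |
| `bumpwm.params` / `bumpwm.network` | network parameters, connectivity, dynamics, bump readout |
| `bumpwm.calibrate` | probes that validate the shipped default parameters |
| `bumpwm.stimdist` | discrete stimulus distributions (`uniform`, skewed, `bimodal`, ...) |
| `bumpwm.task` | trial/session protocol, decisions, jump detection, CSV schema |
| `bumpwm.analysis` | performance matrices, psychometric curves, bias scores, n-back slopes, bump origins, recall |
| `bumpwm.observers` | replacement and Bayesian observers + MSE fitting |
| `bumpwm.glm` | choice GLM, bump regression, geometric-decay analysis |
| `bumpwm.synth` | synthetic-behavior generator with planted effects |
| `bumpwm.experiments` / `bumpwm.cli` | named presets, manifests, command line |

See `docs/methods.md` for the scientific specification, the calibration
of the default parameters, and known limitations.
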