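# Methods

## Model definition

Two populations of `N` rate neurons form one-dimensional line attractors
with free boundary conditions.  Neuron `i` has firing field
`x_i = i/N`.  The firing rate is the logistic readout of the input,
`r_i = 1/(1 + e^{−β h_i})`, so rates live strictly in (0, 1).  Inputs
integrate as

    τ_h^W dh_i^W/dt + h_i^W = Σ_{j≠i} J_ij r_j^W + J_{P→W} r_i^P + I_i^ext
    τ_h^P dh_i^P/dt + h_i^P = Σ_{j≠i} J_ij r_j^P − θ_i + I_i^ext
    τ_θ   dθ_i/dt   + θ_i   = D r_i^P

with shared recurrent weights

    J_ij = (K_ij − J_0) / d_0,     K_ij = J_e exp(−|x_i − x_j| / d_0),

zero self-coupling, and uniform inhibition `J_0`.  The `1/d_0` rescaling
keeps the summed kernel approximately invariant when the interaction
range changes.  A stimulus `s ∈ [0,1]` is a unit-amplitude box over the
firing-field window `[s − δ_s, s + δ_s)` (half-open, index-arithmetic
boundaries, clipped at the ends of the line), driving both networks
identically.  Integration is forward Euler; the reference step is
`dt = 1 ms`.  A coarse 2 ms step is used for the scaled-down session
simulations after a convergence check (bump position change under step
halving below a tenth of the bump width; exercised in the test suite).

The two evaluation paths for the recurrent term — explicit N×N matrix
product and an O(N) two-pass recursion that exploits the exponential
kernel — are algebraically identical; the session runner uses the
recursion (numba-compiled), and a test pins the two paths to each other
at 1e−9.

## Default parameters and how they were calibrated

The synaptic constants are free; the defaults were found by a search
whose acceptance conditions are the probes in `bumpwm.calibrate`:

1. an isolated WM network holds a stimulus-evoked bump ≥ 10 s with
   drift below the bump width, and a single 400 ms stimulus at a new
   location displaces the bump there;
2. an established PPC bump is *not* displaced by a single 400 ms
   stimulus (the slow integration filters brief inputs);
3. at `τ_θ = 7.5 s` the PPC is *stable* for small `D`, *drifts while
   persisting* at `D = 0.3` (the operating point), and *dissipates* for
   large `D`.  Because a perfectly symmetric bump sits at an unstable
   symmetric point of the drift mode, the regime probe displaces the
   established bump off its own adaptation field and then tracks
   survival time and drift speed.

Shipped values at the reference size `N = 300`:

| parameter | symbol | value | units |
| --- | --- | --- | --- |
| neuronal gain | β | 4.6154 | – |
| excitation amplitude | J_e | 0.00377 | input |
| inhibition | J_0 | 0.0010855 | input |
| interaction range | d_0 | 0.05 | attractor length |
| stimulus half-width | δ_s | 0.03 | attractor length |
| WM input timescale | τ_h^W | 0.05 | s |
| PPC input timescale | τ_h^P | 2.0 | s |
| adaptation timescale | τ_θ | 7.5 | s |
| adaptation amplitude | D | 0.3 | input |
| PPC→WM coupling | J_{P→W} | 2.925 | input |
| initial input | h_init | −10/β | input |

Because a neuron's recurrent input sums over ~`N·d_0` active
neighbours, the synaptic amplitudes (`J_e`, `J_0`, `J_{P→W}`) scale as
`1/N`; `default_wm_params(n)` / `default_ppc_params(n)` apply this so
that other network sizes (the regime probes run at N = 500) keep the
same bump physics.  The initial condition `h = −10/β` realizes the
near-zero-rate start without redefining the transfer function; with
these weights the homogeneous low-rate state is stable in the absence
of stimulation (baseline peak rate ≈ 0.14).

## Task protocol

A session is a sequence of trials `[ITI][s1 400 ms][delay][s2 400 ms]`
with **no state reset between trials**; the ITI clock runs from s2
offset to the next s1 onset.  The default protocol draws the delay
uniformly from {2, 6, 10} s (interleaved design; a block design fixes
it), uses a fixed 5 s ITI, and reads the WM activity 200 ms before and
200 ms after s2 onset.  The choice is "s1<s2" when the later readout
sits higher on the line; exact ties are a fair coin from the session's
random stream.  Trials whose readout found no bump are kept in the
table with NaN positions rather than dropped.

The default stimulus set places `s1` on the 5-point grid
{0.3, 0.4, 0.5, 0.6, 0.7} with `s2 = s1 ± 0.2`, plus psychometric pairs
(10% of trials) at offsets ±{0.02, 0.04, 0.08} around the median.  Two
constraints shaped this choice: all `s2` stay in [0.1, 0.9], away from
the free boundaries (bumps at the line ends get clipped recurrent
support and lose readout competitions, which produces spurious ties);
and the pair displacement (0.2) exceeds the bump width (~0.15), so a
PPC bump that tracks the stimulus stream moves by more than its own
width and is correctly classified as a jump.

**Jump bookkeeping.**  `detect_jumps` implements the generic rule
(flag when consecutive readouts differ by more than the bump width).
The per-trial `ppc_jump_prev` column compares the *start-of-trial* PPC
position with the previous trial's mid-delay readout, so the flag marks
trials whose stored PPC value was replaced during the previous trial —
exactly the trials on which a fresh, non-adapted PPC bump faces the
current memory.

## What the circuit reproduces, and one known departure

With the defaults, scaled sessions (N = 300, dt = 2 ms, 120–250 trials)
show: monotone contraction-bias error patterns on both sides of the
diagonal; a negative one-back bias slope whose magnitude grows with the
delay, as do the Bias± scores; bias carried by post-jump trials;
near-perfect performance and no serial dependence when the PPC→WM
coupling is cut; no jumps and no serial dependence (but degraded
performance) when adaptation is removed; and accuracy rising / bias
falling as the ITI grows, with the lag-1 attraction surviving at long
ITIs while lags ≥ 3 are not attractive (lag 5 is measurably repulsive).

Known departure: overall accuracy *increases* with the interstimulus
delay here, because late in a long delay the PPC has usually taken over
the current `s1` and its input then restores rather than corrupts the
memory.  The bias-related delay orderings all have the expected sign;
only the raw accuracy ordering differs, and no test asserts it.

A second departure, kept as a failing test: with adaptation knocked out
(`D = 0`) the PPC bump, which nothing can extinguish or move, parks
permanently near the stimulus mean.  Its fixed coupling input makes any
pair whose `s2` lies at the parked location a readout coin flip, so the
*binary* error pattern is no longer monotone in `s1` even though the
continuous memory displacement remains clearly contractive.

## Observer models

*Replacement model.*  `P(error | s1, s2) = ε · [p_m(s2)/2 + Σ_{wrong
side} p_m]`, with the half-weight tie for a replacement landing exactly
on `s2`; an `s2` between the points of a *uniform* grid simply has no
tie mass, while off-grid `s2` on a nonuniform grid is refused rather
than interpolated.  The optional lapse composes symmetrically:
`P(correct) = (1−δ)(1−p_e) + δ/2`.  The replacement distribution
defaults to the task's marginal stimulus distribution.

*Bayesian observer.*  Likelihood `r1 ~ N(s1, σ)`, exact `s2`, prior
`p_m` on the stimulus grid; report "s1<s2" when the posterior mass
below `s2` (again with half weight at `s2`) exceeds 1/2.  The Gaussian
location family has a monotone likelihood ratio, so that mass is
monotone in `r1` and the decision region is a half-line `r1 < r*`; the
implementation bisects for `r*` and returns the exact Gaussian tail
`Φ((r*−s1)/σ)`.  A fixed-grid quadrature of the same integral is kept
as a cross-check path, and tests verify both against a Monte-Carlo
oracle.

*Fitting.*  Minimum mean-squared error between empirical and predicted
per-pair accuracies.  For the replacement model the MSE is quadratic in
`ε` at fixed `δ`, so `ε` is solved in closed form on a lapse grid
(step 0.0025 on [0, 0.2]); for the Bayesian model a 25-point geometric
`σ` grid on [0.01, 1] with local refinement is used.  Degenerate curve
sets (all pairs sharing one replacement mass) are flagged
non-identifiable.

## Trial-history GLM

The design orients the difficulty covariate as `s2 − s1` so that a
positive `α` means correct behavior.  History covariates are
`(s̄_{t−i} − s1_t)` for `i = 1..h` (default `h = 4`) and
`(⟨s⟩_t − s1_t)` with the running mean over both stimuli of all trials
up to and including the current one (a switch excludes the current
trial).  Fits are unregularized maximum likelihood; separation or rank
deficiency is reported, never silently penalized.  The bump-location
regression is the OLS analogue with regressand `loc − s1` and no
difficulty term.  The geometric-decay fit is log-linear least squares
on `|w_i|` (requiring at least three same-sign lags) and the mean
weight implied by a truncated geometric kernel is `w_{h+1}/(1−γ)`,
tested as an ordering/correlation claim, not an equality.

## Synthetic behavior generator

Emulates the human protocol: ~400 trials, delays {2, 4, 6} s, self-paced
ITIs from a two-lognormal mixture (modes ~1 s and ~5.5 s, mixed 0.55 /
0.45, density dip at the 3 s short/long boundary).  Per trial the
remembered `s1` is replaced with probability `ε(delay, ITI)` —
logistic-linear in both arguments, rising with delay, falling with ITI —
by either the s2 of lag `k` (planted kernel `q_k`) or a fresh marginal
draw; the choice is optimal on the possibly-replaced memory, then
lapsed.  Stimuli stay abstract amplitudes in [0, 1]; no audio is
synthesized, since every analysis operates on normalized values.  What
the generator does *not* emulate: perceptual noise on `s2`, learning or
drift of the decision criterion, and subject heterogeneity — so passing
recovery tests demonstrate estimator correctness, not robustness to
those real-data features.

## Problem sizes and numerical choices

The test suite simulates at `N = 300`, `dt = 2 ms`, 120–250 trials per
session and 3–12 seeds per condition; the regime probes run at
`N = 500`, `dt = 1 ms`.  Bootstrap CIs are percentile, 200–1000
resamples, seeded.  Bump width is the full width at half height above
the 10th-percentile baseline; a profile whose range is below 1e−3 is a
no-bump sentinel (NaN), never a silent zero.  The bump-origin window is
±5% of the line; the analytic chance levels (`Σ p_m²` for stimulus
targets, `p_m(mean)` for the mean target) assume the bump-location
marginal tracks `p_m`, which holds to within a few percent on intact
sessions — the shuffle-based check in the suite uses ~450-trial
subsamples, where that approximation is well inside the binomial noise.

## Limitations

* Rate neurons, 1-D attractors, no spiking, no synaptic facilitation,
  no periodic boundaries.
* The calibrated operating point is one solution to the stated
  constraints, not a unique one; amplitudes must be rescaled (done
  automatically) when changing `N`, and behavior at very small `N`
  (< ~100) is dominated by discretization.
* The adaptation knock-out degeneracy and the accuracy-vs-delay
  direction described above.
* Observer fits assume the replacement distribution is known (the task
  marginal); fitting it jointly is out of scope.
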