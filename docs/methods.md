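# Methods

## Model

The divisive-normalization accumulator is the coupled system

    tau_R dR_i/dt = -R_i + C_i/(1 + G),      i in {left, right}
    tau_G dG/dt   = -G + omega_I (R_left + R_right)

with both units starting at 0 at stimulus onset (the derivation of the
kernel integrates from 0 with no initial-state term, and the inter-trial
interval is assumed long enough for the circuit to relax).  The pool size
is fixed at N = 2; the inhibitory sum is not generalized to more
alternatives.  `delta = R_left - R_right` is linear in the signed input
stream `Delta-C = C_left - C_right`, which gives the analytic integration
kernel

    delta(T) = int_0^T K(T, t') Delta-C(t') dt',
    K(T, t') = (1/tau_R) exp(-(T - t')/tau_R) / (1 + G(t')).

### Click-input convention

The click train is treated as the unit-height evidence stream `Delta-C(t)`
(+1 or -1 throughout each slot), delivered numerically as one punctate
impulse per click carrying its slot's evidence mass `a` (the inter-click
interval, 0.05 s by default; a single isolated click spans the stimulus).
Integrating the R equation across an impulse gives the jump
`a/(tau_R (1 + G(t-)))`, with G evaluated just before the impulse (the
impulse cannot see inhibition it has not yet caused) and continuous across
it (the G equation receives no impulse input).  This convention was chosen
over unit-area impulses after checking both against the exemplar
parameter set (tau_R = 2.27 s, tau_G = 11.10 s, omega_I = 36.20): with
slot-mass impulses that setting produces the expected interior
(bump-shaped) kernel peaking near click 8, whereas unit-area impulses
drive G so hard that every kernel in the family is effectively monotone.
Because the choice rule divides by the free noise `sigma` and adds the
free offset `mu`, the two conventions index the same model family; the
slot-mass convention simply makes the published exemplar live in the
intended regime.  Time is in seconds throughout; the exemplar tau values
are read as seconds.

### Choice rule

    logit p(left) = [sum_i (a K(T, t_i) + mu) sign_i] / sigma + bias

A logistic (not probit) link is used, as written.  Likelihoods clip
probabilities to [1e-10, 1 - 1e-10] so extreme parameters stay finite;
the clip is a module constant (`divnorm.PROB_CLIP`).

## Numerics for the circuit

Between clicks the smooth system is advanced by classical fixed-step RK4
with grid nodes forced at every click time; default dt = 1e-3 s, validated
against a dt = 1e-5 re-integration.  Because the total drive (one impulse
per slot regardless of side) is shared by all trains of a fixed-grid
protocol, G — and hence the 20 kernel values — depends only on
(tau_R, tau_G, omega_I) and the timing; `gain_trajectory` integrates the
reduced (A, G) system, A = R_left + R_right, with the same RK4 stepper, so
it agrees with the full simulation to rounding error, and kernel values
are memoized per parameter set.  The fitting path evaluates the kernel at
dt = 2.5e-3 s (RK4 error is far below the likelihood's resolution there);
reported likelihoods at the default dt differ negligibly.

## Benchmark accumulators

The DDM/LCA family `da = (lam a + C) dt + sigma_a dW` treats each click as
a unit kick.  Without a bound, `a(T)` is Gaussian — mean
`sum_i sign_i e^{lam (T - t_i)}`, variance
`sigma_a^2 (e^{2 lam T} - 1)/(2 lam)` (its `lam -> 0` limit
`sigma_a^2 T`) — so the choice probability is a closed-form normal CDF.

The bounded adaptive model propagates the accumulator density on a uniform
grid over [-B, +B] (default 501 nodes; the dt default is 0.0125 s, four
sub-steps per inter-click interval):

- **Transition step.** Each step applies the exact Ornstein–Uhlenbeck
  transition kernel (mean stretch `x e^{lam dt}`, the Gaussian step
  standard deviation above) integrated over destination cells.  Column
  sums are one by construction, so mass is conserved to rounding error.
  Two corrections make the scheme accurate at coarse resolution:
  Sheppard's correction (the kernel is narrowed by dx^2/12 of variance to
  cancel the cell-centre discretization bias) and a Brownian-bridge
  within-step absorption term (paths from x to y may have touched a bound
  inside the step with probability `exp(-2 (B-x)(B-y)/s^2)`).  With both,
  the solver matches the unbounded Gaussian closed form to ~1e-4 and a
  halve-dt/double-nodes refinement changes choice probabilities by
  < 5e-4 on the reference battery (lam in [-2, 2], sigma_a in [0.7, 2],
  bias in [-1, 1], B = 5 and B = 50).
- **Stability criterion.** With nonzero drift the one-step kernel must
  resolve the grid (`s >= dx/2`), otherwise the drift would be rounded
  away; violating configurations raise an error carrying the admissible
  dt.  With `lam = 0` a sub-cell kernel degenerates gracefully to the
  identity.
- **Clicks** shift the density by their signed, adaptation-scaled
  magnitude with linear re-binning; mass pushed past a bound is absorbed
  there and never returns (sticky-bound semantics — evidence after
  crossing is ignored).  Integer-cell shifts (magnitude 1 with the default
  grids) are exact.
- **Readout.** p(left) = mass absorbed at +B plus interior mass above the
  bias threshold; the cell straddling the threshold is split linearly (a
  node exactly at the threshold contributes half its cell — a
  measure-zero tie, resolved symmetrically).

Sensory adaptation is per side, as described for this task (successive
clicks *on the same side*): a state starting at 1 multiplies the click's
magnitude, is then scaled by phi, and relaxes to 1 with time constant
tau_phi; the sides do not interact.  phi = 1 is exactly neutral, so the
bounded-LCA variant is the same code with adaptation switched off.

## Kernel regression and shape classification

The integration kernel is estimated by Newton/IRLS logistic regression of
choice on the 20 signed clicks plus an intercept (convergence when the
score's sup-norm falls below 1e-8, at most 100 iterations), with an
optional L2 penalty on the click weights only.  Standard errors come from
the observed (penalized) information.  If the converged fit classifies
every trial correctly the data are perfectly separated and the unpenalized
MLE does not exist; this raises an error advising a small ridge (1e-3),
and the command-line pipeline falls back to that ridge automatically with
a warning.  The implementation is cross-checked against an independent
logistic-regression fit in the test suite.

Shape labels use a deterministic heuristic on the weight profile: with
early/middle/late segment means e, m, l (clicks 1–5, 8–13, 16–20), overall
mean g, and threshold theta = 0.15 |g| — flat if all pairwise contrasts
are within theta; else bump if m exceeds both e and l by theta; else
primacy (e > l + theta) or recency (l > e + theta); else flat.  The
windows and flatness fraction are configuration, not a claim about any
published procedure; the rule is scale-invariant, so analytic kernels are
classified on the `a K + mu` scale without knowing sigma.

## Synthetic cohorts

The generator emulates the study protocol exactly: 20 clicks per 1-s
trial on a fixed 50-ms grid (first click at t = 0 — the original
experiment does not state the origin; this convention makes the
click-to-decision spans (0.05, 1.0] s), clicks on the designated correct
ear with probability 0.55, correct side left with probability 0.5, a fixed
750 trials per participant in place of the original stopping rule
(stopping rules do not enter the likelihood), and a 60% accuracy inclusion
threshold.  Cohorts draw one child random stream per participant from the
cohort seed, so a participant's data are invariant to cohort size; group
sizes follow largest-remainder allocation of the mixture (the default
0.31/0.53/0.12/0.04 reproduces 41/71/16/5 at n = 133).

Each shape group has a calibrated prior box for the observer parameters
(see `task.DEFAULT_PARAMETER_PRIORS`): primacy lives at high tau_R/tau_G
with strong inhibition; the bump group sits on the narrow ridge where
leak, inhibition, and a negative kernel offset mu balance (its mu is
drawn relative to the drawn kernel's own minimum, the only way to keep
the whole box inside the bump label); flat uses long time constants and
weak inhibition; recency uses short tau_R.  Every corner of every box was
verified to classify as its group's label, and sigma ranges put simulated
accuracy at 0.60–0.70 — realistic because an ideal counter only reaches
~0.71 when each click is 55% valid.  What the generator does **not**
emulate: session effects (learning, fatigue, lapses), reaction times,
between-trial dependencies, and any within-participant parameter drift —
so passing recovery tests show the estimation machinery is sound under
the model, not that real data satisfy it.

## Fitting

All models are fitted by multi-start bounded maximum likelihood:
`n_starts` L-BFGS-B runs (numerical gradients) from uniform random starts
in the (log-transformed) bounding box, positive-scale parameters on the
log scale, best endpoint kept.  Starts are drawn sequentially from the
seeded generator, so the best likelihood is nondecreasing in `n_starts`
for a fixed seed.  Endpoints within 1e-6 (transformed units) of a bound
are flagged.  The default box (`fitting.MODEL_SPECS`) is deliberately
wide; the recovery experiment uses a documented weakly-informative box
(`fitting.DEFAULT_RECOVERY_BOUNDS`) spanning the psychophysically
plausible regime for a 1-s stimulus.  The default 50 restarts (the
original analysis used ~360) is backed by the monotone-restart property
and by refits reaching likelihoods at or above the generating parameters'.

### A structural identifiability limit

The kernel *shape* is well identified: in every recovery experiment run
during development, the shape label of the refitted analytic kernel
matched the generating group for 100% of participants.  The *ratio*
tau_R/tau_G is not point-identified from binary choices: whenever
inhibition barely shapes the kernel (flat and recency phenotypes),
omega_I -> 0 removes tau_G from the model entirely, and distinct
(tau_R, tau_G, omega_I, mu) sets produce weight profiles equal to within
sampling noise, so the ML estimate wanders along iso-likelihood ridges
(reaching likelihoods at or above the truth while landing far away in
ratio).  Rank correlations between true and recovered log ratios across
a small mixed cohort are therefore unstable (0.1–0.8 across designs and
seeds), and the corresponding recovery-experiment check is expected to
fail; the report states the measured correlation honestly.  This mirrors
the empirical observation that flat- and recency-kerneled participants
are indistinguishable in fitted log ratio.

## Problem sizes in the test suite

Unit tests use 10^2–10^4 trials; the protocol-statistics check uses
10,000 trials; kernel-recovery checks use 20,000–50,000 trials; the LCA
phenotype sweep uses 50,000 trials per lam and 20,000 per grid point; the
cohort recovery experiment uses 12 participants x 5,000 trials x 50
restarts (about two minutes end to end).  These sizes were chosen so each
statistical assertion has comfortable power at its stated tolerance.

## Known limitations

- Interrogation paradigm only: no reaction-time (first-passage)
  likelihoods; the decision is read out at the fixed stimulus end.
- Two alternatives only, and a single stimulus duration; choice noise is a
  single time-invariant sigma.
- The fixed-grid protocol is assumed wherever per-protocol kernel caching
  is used (guarded by an equivalence test); Poisson-timed click trains are
  representable in the containers but not generated.
- The shape classifier is a transparent heuristic; labels near regime
  boundaries are sensitive to its flatness fraction (0.15 by default,
  always stated where it matters).
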