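# clicknorm

Models of how people weigh evidence over time in an auditory
two-alternative decision task, centred on **dynamic divisive
normalization** as an evidence-accumulation circuit, with
drift-diffusion-family competitors and the full estimation pipeline
(integration-kernel regression, multi-start maximum likelihood, AIC/BIC
model comparison) needed to study them — all runnable on synthetic cohorts
with no data download.

## The task and the question

On each trial an observer hears 20 clicks over 1 s, one every 50 ms, each
delivered to the left or right ear.  One side is designated "correct" with
probability 0.5 and each click lands on that side with probability 0.55;
at stimulus end the observer reports which ear received more clicks.  The
scientific question is the **integration kernel**: how much does the click
in slot *i* contribute to the final choice?  Real cohorts show four
phenotypes — primacy (early clicks dominate), recency (late clicks),
flat (equal weighting, the ideal strategy), and, most commonly, a **bump**
that peaks mid-stimulus.

## The model

Two excitatory pools receive the left and right click streams and are
divisively inhibited by a gain-control unit `G` driven by their summed
activity:

```
tau_R dR_i/dt = -R_i + C_i / (1 + G)          i in {left, right}
tau_G dG/dt   = -G + omega_I (R_left + R_right)
```

The decision variable `delta = R_left - R_right` obeys a linear equation,
so at decision time `T` it is an explicit weighted sum of the signed
clicks with analytic kernel

```
K(T, t') = (1/tau_R) exp(-(T - t')/tau_R) / (1 + G(t'))
```

— the product of a *rising* exponential (leaky integration forgets early
clicks) and the *falling* `1/(1+G)` (inhibition builds and suppresses late
clicks).  The balance between the two rates, the ratio `tau_R/tau_G`,
moves the kernel through primacy, bump, flat, and recency regimes.  Choice
is read out as `logit p(left) = (sum_i (a*K_i + mu) sign_i)/sigma + bias`,
with click evidence mass `a` (one 50-ms slot), kernel offset `mu`, noise
`sigma`, and a side bias — six free parameters in total.

Competitors, each with an exact or density-propagation likelihood: the
basic DDM (`da = C dt + sigma_a dW`, flat kernel), the LCA with memory
drift `lam` (recency for `lam < 0`, primacy for `lam > 0`, never a bump),
and the six-parameter bounded adaptive accumulator (sticky bound `B`,
per-side sensory adaptation `phi`, `tau_phi`).

## Worked example

```python
import numpy as np
from clicknorm import (TaskProtocol, DivNormParams, DivNormObserver,
                       generate_dataset, simulate_choices,
                       fit_logistic_kernel, classify_kernel_shape)

proto = TaskProtocol()                       # 20 clicks / 1 s, p = 0.55
params = DivNormParams(tau_R=2.27, tau_G=11.10, omega_I=36.20,
                       sigma=0.001, mu=-0.0128, bias=0.0)
rng = np.random.default_rng(0)
data = generate_dataset(proto, 3000, rng)
data = simulate_choices(data, DivNormObserver(params, proto), rng)
print(f"accuracy: {data.accuracy():.3f}")
est = fit_logistic_kernel(data)
print(f"kernel peak at click {est.beta_click.argmax() + 1} of 20")
print(f"kernel shape: {classify_kernel_shape(est).label}")
```

prints

```
accuracy: 0.675
kernel peak at click 7 of 20
kernel shape: bump
```

The simulated observer is about 67% correct (an ideal counter tops out
near 71% when each click is only 55% valid), and the model-free logistic
regression recovers a mid-stimulus bump — the signature the divisive
circuit produces when leak and inhibition are balanced as above.

Model fitting uses scikit-learn-style estimators:

```python
from clicknorm import DivisiveNormalizationModel, LeakyAccumulatorModel

X, y = data.signs_matrix(), data.choices_binary()
dn = DivisiveNormalizationModel(n_starts=50, random_state=0).fit(X, y)
lca = LeakyAccumulatorModel(n_starts=50, random_state=0).fit(X, y)
print(dn.aic_, lca.aic_)     # lower is better; dn wins on bump observers
```

A `clicknorm` console script exposes the pipeline
(`simulate`, `kernel`, `fit`, `compare`, `recover`), each taking
`--config`, `--seed`, and `--out`.

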