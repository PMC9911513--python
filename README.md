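# predabc

Posterior *predictive* inference for intractable simulator models via
approximate Bayesian computation (ABC).

Standard ABC approximates the parameter posterior π(θ | y) using only
forward simulations. This package is for the follow-up question
practitioners actually care about — *what happens next?* — when the
posterior predictive

    π(ỹ | y) = ∫ π(ỹ | y, θ) π(θ | y) dθ

is doubly intractable: neither the likelihood nor the conditional
predictive density π(ỹ | y, θ) can be evaluated, and often the latter
cannot even be simulated. It implements three complementary
approximations:

| method | needs to simulate | summary statistic should be |
|--------|-------------------|-----------------------------|
| ABC-F  | π(ỹ \| y, θ) and π(y \| θ) | parameter sufficient |
| ABC-P  | (ỹ, y) \| θ jointly        | *predictive* sufficient |
| ABC-L  | (y, v) \| θ and π(ỹ \| y, v, θ) | sufficient for (θ, v) |

ABC-F is the classical two-stage route (ABC for θ, then direct
conditional simulation). ABC-P accepts jointly simulated (data,
prediction) pairs on summarized data, and targets π(ỹ | s_y) as the
threshold h → 0 — which equals π(ỹ | y) only if s is predictive
sufficient, a strictly stronger condition than parameter sufficiency for
dependent data. ABC-L infers latent variables jointly with θ and predicts
through them. All three share rejection, self-normalized importance
sampling (weight K_h(Δ)·π(θ)/q(θ)) and random-walk ABC-MCMC samplers on
the augmented target; the acceptance ratio never involves ỹ, so
predictions can be deferred to retained draws.

Audience: statisticians and computational biologists doing
simulation-based inference on dynamic models (epidemic, queueing,
ecological, biochemical-network) who need calibrated forecasts or
missing-data reconstruction, not just parameter estimates.

Four worked models are bundled, each a first-class tested simulator:

* **AR(1) chain** with closed-form Gaussian oracles for every ABC
  quantity (`predabc.ar1`) — the validation backbone;
* **linear-Gaussian state-space model** with exact sufficiency identities
  via joint-normal conditioning (`predabc.ssm`);
* **M/G/1 queue** — predict future customers' waiting times from
  interdeparture times only (`predabc.mg1`);
* **stochastic Lotka–Volterra** predator–prey Markov jump process with an
  exact (numba-accelerated) Gillespie simulator (`predabc.lv`).

## Worked example

`examples/ar1_closed_forms.py` infers the drift c of
y_t = c + 0.5·y_{t−1} + N(0, 1) from n = 100 observations (c_true = 1)
with Gaussian-kernel (h = 0.1) ABC importance sampling on the sufficient
weighted average, then predicts y₁₀₁ by the two-stage route:

```
posterior of c   : sampled mean 1.0803, var 0.02008
closed form      : mean 1.0811, var 0.02000
  (kernel bandwidth h inflates the exact posterior variance sigma^2/n by h^2)
predictive y_101 : sampled mean 1.0034, var 0.9996
closed form      : mean 1.0142, var 1.0200
  (two-stage prediction: the same h is much less harmful here, h^2 vs sigma^2 (1 + 1/n))
```

The sampled moments match the closed forms N(ȳ_φ, σ²/n + h²) and
N(ȳ_φ + φy₁₀₀, σ²(1 + 1/n) + h²) to Monte-Carlo accuracy — and the two
variance formulas show why a bandwidth that badly degrades the
*posterior* barely touches the *predictive*.

The other examples each run in a few minutes:

* `ar1_summary_dissociation.py` — parameter sufficiency ≠ predictive
  sufficiency, as KS distances under three summary choices;
* `ssm_sufficiency.py` — exact sufficiency identities in the state-space
  model;
* `mg1_waiting_times.py` — the baseline queue summary loses the ordering
  of the data and produces a far too heavy right tail for the next
  waiting time;
* `lv_prediction.py` — forecasting both populations of a predator–prey
  system: ABC-F ≪ ABC-P in median-forecast error when the state at the
  forecast origin is observed.

See `docs/methods.md` for the estimators, calibration procedures,
parameter defaults and known limitations.

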