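"""AR(1) drift inference: ABC samplers against closed-form Gaussian answers.

Simulates n = 100 observations of y_t = c + 0.5 y_{t-1} + N(0, 1) at c = 1,
runs Gaussian-kernel ABC importance sampling on the sufficient weighted
average, and compares the weighted posterior moments of c -- and the
two-stage (ABC-F) predictive moments of y_101 -- with the exact formulas.
"""

import numpy as np

from predabc import (
    DiscrepancySpec,
    GaussianProposal,
    KernelSpec,
    SingleKernelRule,
    UniformBoxPrior,
    abc_f_predict,
    abc_importance,
)
from predabc.ar1 import (
    AR1Model,
    ar1_abc_posterior_c,
    ar1_predictive_oracle,
    ar1_summaries,
    ar1_summary_spec,
)

model = AR1Model(phi=0.5, sigma2=1.0, n=100, n_future=1)
rng = np.random.default_rng(0)
y = model.simulate_obs(np.array([1.0]), rng).y
ybar = float(ar1_summaries(y, 0.5, "s1")[0])

h = 0.1
rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("gaussian", h))
run = abc_importance(model, UniformBoxPrior([-50.0], [50.0]),
                     GaussianProposal([ybar], [0.5]), ar1_summary_spec(0.5, "s1"),
                     rule, y, m=50_000, seed=1)
c, w = run.thetas[:, 0], run.weights
mean, var = float(np.sum(w * c)), float(np.sum(w * (c - np.sum(w * c)) ** 2))
target = ar1_abc_posterior_c(ybar, 1.0, 100, h)
print(f"posterior of c   : sampled mean {mean:.4f}, var {var:.5f}")
print(f"closed form      : mean {target.mean:.4f}, var {target.variance:.5f}")
print("  (kernel bandwidth h inflates the exact posterior variance "
      "sigma^2/n by h^2)")

pred = abc_f_predict(run, model, y, seed=2)
yp = pred.ytilde[:, 0]
pm = float(np.sum(w * yp))
pv = float(np.sum(w * (yp - pm) ** 2))
ptarget = ar1_predictive_oracle(y, 0.5, 1.0, h, "abc_f")
print(f"predictive y_101 : sampled mean {pm:.4f}, var {pv:.4f}")
print(f"closed form      : mean {ptarget.mean:.4f}, var {ptarget.variance:.4f}")
print("  (two-stage prediction: the same h is much less harmful here, "
      "h^2 vs sigma^2 (1 + 1/n))")
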