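"""Exact sufficiency identities in a linear-Gaussian state-space model.

The latent chain v_t = c + 0.5 v_{t-1} + N(0,1) is observed through
y_t = v_t + N(0, 0.7). Two scalar statistics are computed from y:
s1 = mu^T W^-1 y (minimal parametric sufficient for c) and
s2 = Sigma_{n,:} W^-1 y. Prints the exact posteriors of c and of y_{n+1}
under different conditioning sets, verifying that s1 alone recovers the
posterior of c, that a fixed linear combination of (s1, s2) recovers the
predictive, and that s1 alone does not.
"""

import numpy as np

from predabc.ssm import (
    SSMModel,
    SSMParams,
    ssm_exact_posterior,
    ssm_predictive_sufficient_combo,
    ssm_summaries,
)

params = SSMParams(phi=0.5, sigma2=1.0, omega2=0.7, n=20)
rng = np.random.default_rng(3)
y = SSMModel(params).simulate_obs(np.array([1.0]), rng).y
s1, s2 = ssm_summaries(y, params)
print(f"summaries: s1 = {s1:.4f}, s2 = {s2:.4f}")

for given in ("full", "s1"):
    d = ssm_exact_posterior(y, params, "c", given=given)
    print(f"posterior of c given {given:>4}: N({d.mean:.4f}, {d.variance:.5f})")

alpha, beta = ssm_predictive_sufficient_combo(params)
print(f"\npredictive-sufficient combination: {alpha:.4f} * s1 + {beta:.4f} * s2")
for given in ("full", "s1"):
    d = ssm_exact_posterior(y, params, "y_next", given=given)
    print(f"predictive of y_21 given {given:>4}: N({d.mean:.4f}, {d.variance:.4f})")
print("(conditioning on s1 alone inflates the predictive variance: "
      "parametric sufficiency does not imply predictive sufficiency)")
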