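"""AR(1) Markov chain with closed-form Gaussian oracles.

The model is the discrete-time process

    y_t | y_{t-1}, c  ~  N(c + phi * y_{t-1}, sigma^2),   y_0 = 0,

with drift ``c`` unknown (flat prior) and ``phi``, ``sigma^2`` fixed. Every
ABC quantity of interest has a closed Gaussian form here, which makes the
model the principal validation oracle of the package:

* the ABC posterior of ``c`` under a Gaussian kernel on the weighted
  average ``ybar_phi`` is N(ybar_phi, sigma^2/n + h^2), recovering the
  exact posterior at h = 0;
* the two-stage (ABC-F) predictive of y_{n+1} is
  N(yring_phi, sigma^2 (1 + 1/n) + h^2) with
  yring_phi = ybar_phi + phi * y_n;
* the joint-simulation (ABC-P) predictive targets for the different
  summary choices follow from exact joint-Gaussian conditioning
  (:class:`predabc.gaussian.FlatLocationGaussian`), treating the Gaussian
  acceptance kernel as additive observation noise on the summary.

Three summary statistics are studied: s1 = ybar_phi (sufficient for c but
not for prediction), s2 = (ybar_phi, y_n) and s3 = yring_phi (sufficient
for predicting y_{n+1} but poor for c). The dissociation between parameter
and predictive sufficiency is the central qualitative phenomenon the
package reproduces.

A separate utility bounds the acceptance probability of matching the last
observation alone, max_c P(|z_n - y_n| <= h_tilde), which decays with n in
the nonstationary regimes |phi| >= 1 and is bounded away from zero when
|phi| < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import Capability, Simulation, SimulatorModel, SummarySpec
from .gaussian import FlatLocationGaussian, GaussianDensity

__all__ = [
    "AR1Params",
    "AR1Model",
    "ar1_mean_vector",
    "ar1_covariance",
    "ar1_summaries",
    "ar1_summary_spec",
    "ar1_abc_posterior_c",
    "ar1_predictive_oracle",
    "ar1_acceptance_bound",
]


@dataclass
class AR1Params:
    """Fixed quantities of the AR(1) experiments (the drift c is inferred)."""

    c: float = 1.0
    phi: float = 0.5
    sigma2: float = 1.0
    n: int = 100

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("innovation variance must be positive")
        if self.n <= 1:
            raise ValueError("need n > 1 observations")


def _ar1_path(c: float, phi: float, sigma: float, y0: float, steps: int,
              rng: np.random.Generator) -> np.ndarray:
    # y_t = phi * y_{t-1} + (c + sigma * eps_t), run as a linear filter
    u = c + rng.standard_normal(steps) * sigma
    y, _ = lfilter([1.0], [1.0, -phi], u, zi=np.array([phi * y0]))
    return y


class AR1Model(SimulatorModel):
    """Simulator with JOINT and COND_PRED capabilities; theta = (c,).

    ``n_future`` future values are appended by continuing the recursion
    from the last simulated (JOINT) or observed (COND_PRED) value, which
    is the exact conditional predictive law of this Markov chain.
    """

    capabilities = frozenset({Capability.JOINT, Capability.COND_PRED})

    def __init__(self, phi: float, sigma2: float, n: int, n_future: int = 1):
        if sigma2 <= 0:
            raise ValueError("innovation variance must be positive")
        if n <= 1:
            raise ValueError("need n > 1 observations")
        self.phi = float(phi)
        self.sigma = math.sqrt(sigma2)
        self.sigma2 = float(sigma2)
        self.n = int(n)
        self.n_future = int(n_future)

    def simulate_obs(self, theta: np.ndarray, rng: np.random.Generator) -> Simulation:
        c = float(np.atleast_1d(theta)[0])
        y = _ar1_path(c, self.phi, self.sigma, 0.0, self.n, rng)
        return Simulation(y=y, state=y[-1])

    def predict_given_state(self, theta: np.ndarray, state: object,
                            rng: np.random.Generator) -> np.ndarray:
        c = float(np.atleast_1d(theta)[0])
        return _ar1_path(c, self.phi, self.sigma, float(state), self.n_future, rng)

    def cond_predict(self, theta: np.ndarray, y_obs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        return self.predict_given_state(theta, float(y_obs[-1]), rng)


def ar1_summaries(y: np.ndarray, phi: float, variant: str) -> np.ndarray:
    """Summary statistics s1 = ybar_phi, s2 = (ybar_phi, y_n), s3 = ybar_phi + phi*y_n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    ybar_phi = ((1.0 - phi) * np.sum(y[:-1]) + y[-1]) / n
    if variant == "s1":
        return np.array([ybar_phi])
    if variant == "s2":
        return np.array([ybar_phi, y[-1]])
    if variant == "s3":
        return np.array([ybar_phi + phi * y[-1]])
    raise ValueError(f"unknown summary variant {variant!r}")


def ar1_summary_spec(phi: float, variant: str) -> SummarySpec:
    """SummarySpec for a variant; s2 is partitioned into (ybar_phi | y_n)."""
    dim = 2 if variant == "s2" else 1
    dim_bar = 1 if variant == "s2" else dim
    return SummarySpec(fn=lambda y: ar1_summaries(y, phi, variant),
                       dim=dim, dim_bar=dim_bar)


def ar1_mean_vector(n: int, phi: float) -> np.ndarray:
    """mu with mu_t = (1 - phi^t)/(1 - phi): E[y_t] = c * mu_t from y_0 = 0."""
    t = np.arange(1, n + 1)
    if phi == 1.0:
        return t.astype(float)
    return (1.0 - phi ** t) / (1.0 - phi)


def ar1_covariance(n: int, phi: float, sigma2: float) -> np.ndarray:
    """Cov(y_s, y_t) = sigma^2 phi^|t-s| (1 - phi^(2 min(s,t))) / (1 - phi^2)."""
    t = np.arange(1, n + 1)
    mins = np.minimum.outer(t, t)
    absdiff = np.abs(np.subtract.outer(t, t))
    if phi in (1.0, -1.0):
        return sigma2 * (phi ** absdiff) * mins
    return sigma2 * (phi ** absdiff) * (1.0 - phi ** (2 * mins)) / (1.0 - phi * phi)


def ar1_abc_posterior_c(ybar_phi: float, sigma2: float, n: int, h: float
                        ) -> GaussianDensity:
    """ABC posterior of c with a Gaussian kernel on ybar_phi: N(ybar_phi, sigma^2/n + h^2).

    h = 0 is the exact posterior under the flat prior.
    """
    if h < 0:
        raise ValueError("bandwidth must be nonnegative")
    return GaussianDensity(float(ybar_phi), sigma2 / n + h * h)


def _summary_rows(n: int, phi: float, variant: str) -> np.ndarray:
    """Linear maps y_{1:n+1} -> summary (zero loading on the future value)."""
    a1 = np.zeros(n + 1)
    a1[: n - 1] = (1.0 - phi) / n
    a1[n - 1] = 1.0 / n
    if variant == "s1_only":
        return a1[None, :]
    if variant == "s3":
        a3 = a1.copy()
        a3[n - 1] += phi
        return a3[None, :]
    if variant == "s2":
        e_n = np.zeros(n + 1)
        e_n[n - 1] = 1.0
        return np.vstack([a1, e_n])
    raise ValueError(f"unknown oracle variant {variant!r}")


def ar1_predictive_oracle(y: np.ndarray, phi: float, sigma2: float, h: float,
                          variant: str) -> GaussianDensity:
    """Closed-form law of y_{n+1} under the named approximation.

    ``abc_f``  : N(yring_phi, sigma^2 (1 + 1/n) + h^2) -- the two-stage
                 predictive that plugs the Gaussian-kernel ABC posterior of
                 c (based on ybar_phi) into the exact transition density.
    ``exact``  : the exact posterior predictive (= abc_f at h = 0).
    ``s1_only``/``s2``/``s3`` : the joint-simulation (ABC-P) targets with a
                 Gaussian kernel of bandwidth h per summary coordinate,
                 obtained by exact joint-Gaussian conditioning of
                 (y_{n+1}, s) under the flat prior on c.
    """
    if h < 0:
        raise ValueError("bandwidth must be nonnegative")
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = float(ar1_summaries(y, phi, "s1")[0])
    yring = ybar + phi * y[-1]
    if variant == "exact":
        return GaussianDensity(yring, sigma2 * (1.0 + 1.0 / n))
    if variant == "abc_f":
        return GaussianDensity(yring, sigma2 * (1.0 + 1.0 / n) + h * h)
    A = _summary_rows(n, phi, variant)
    model = FlatLocationGaussian(ar1_mean_vector(n + 1, phi),
                                 ar1_covariance(n + 1, phi, sigma2))
    t = np.zeros(n + 1)
    t[n] = 1.0
    s_obs = A[:, :n] @ y
    return model.condition_scalar(A, s_obs, h=h, t=t)


def ar1_acceptance_bound(phi: float, sigma2: float, n: int, h_tilde: float
                         ) -> tuple[float, str]:
    """Bound on max_c P(|z_n - y_n| <= h_tilde) for matching the last value alone.

    Returns (value, direction): an *upper* bound when |phi| >= 1 (the bound
    decays like 1/sqrt(n) or faster, so matching becomes arbitrarily hard)
    and a *lower* bound when |phi| < 1 (the stationary case keeps a
    positive matching probability for any n).
    """
    if h_tilde <= 0:
        raise ValueError("h_tilde must be positive")
    if n < 1:
        raise ValueError("need n >= 1")
    base = math.sqrt(2.0) * h_tilde / math.sqrt(math.pi * sigma2)
    a = abs(phi)
    if a > 1.0:
        return base * math.sqrt((phi * phi - 1.0) / (phi ** (2 * n) - 1.0)), "upper"
    if a == 1.0:
        return base / math.sqrt(n), "upper"
    return base * math.sqrt(1.0 - phi * phi) * math.exp(-h_tilde * h_tilde / (2.0 * sigma2)), "lower"
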