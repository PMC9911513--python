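"""M/G/1 queue: likelihood-free inference for future waiting times.

Customers arrive at a single server following a Poisson process with rate
theta_3 (i.i.d. interarrival times w_i ~ Exp(theta_3)); service times are
u_i ~ U([theta_1, theta_2]). Only the interdeparture times

    y_i = u_i + max{0, v_i - x_{i-1}},     v_0 = x_0 = 0,

are observed, where v_i = sum(w_1..w_i) are arrival times and
x_i = sum(y_1..y_i) departure times. The likelihood of y is intractable
but the recursion is trivially simulable, jointly with the waiting times
omega_i = x_i - v_i (time from arrival to departure, service included)
of future customers -- the prediction target. The arrival times v are the
latent variables: the queue state after customer n is (x_n, v_n), so both
the joint law (y, v, omega-tilde) | theta and the conditional predictive
pi(omega-tilde | x_n, v_n, theta) can be simulated, enabling ABC-P and
ABC-L (but not ABC-F).

Summary statistics: the 5-dimensional baseline s0 stacks the 0.25/0.5/0.75
empirical quantiles of y with its range encoded as the pair (min, max)
(keeping s0 5-dimensional; a scalar max-min would give four). The extended
s1 appends, for threshold quantiles 0.7/0.8/0.9 of the *observed* data,
the index of the last interdeparture time exceeding that threshold
(max empty-set = 1): recent large gaps signal an empty queue, which is
what matters for predicting the next waiting times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Capability, Prior, Simulation, SimulatorModel, SummarySpec

__all__ = [
    "MG1Params",
    "QueueTrajectory",
    "MG1Model",
    "mg1_recursion",
    "mg1_simulate",
    "mg1_conditional_predict",
    "mg1_summaries",
    "mg1_summary_spec",
    "MG1Prior",
]


@dataclass
class MG1Params:
    """theta = (theta1, theta2, theta3): service-time bounds and arrival rate."""

    theta1: float
    theta2: float
    theta3: float

    def __post_init__(self) -> None:
        if not 0 <= self.theta1 <= self.theta2:
            raise ValueError("need 0 <= theta1 <= theta2")
        if self.theta3 <= 0:
            raise ValueError("arrival rate must be positive")

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "MG1Params":
        t = np.atleast_1d(np.asarray(theta, dtype=float))
        return cls(float(t[0]), float(t[1]), float(t[2]))


@dataclass
class QueueTrajectory:
    """Full bookkeeping of one simulated queue path."""

    y: np.ndarray      # interdeparture times
    v: np.ndarray      # arrival times
    x: np.ndarray      # departure times
    u: np.ndarray      # service times
    omega: np.ndarray  # waiting times x_i - v_i


def mg1_recursion(u: np.ndarray, w: np.ndarray, x0: float = 0.0, v0: float = 0.0
                  ) -> QueueTrajectory:
    """Run the queue recursion for given service and interarrival times.

    Starting from queue state (x0, v0); the injected randomness makes the
    recursion directly checkable by hand and lets a joint simulation be
    split into an observed segment plus a conditional continuation.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    k = u.size
    if w.size != k:
        raise ValueError("need one interarrival time per customer")
    y = np.empty(k)
    v = np.empty(k)
    x = np.empty(k)
    omega = np.empty(k)
    x_prev, v_prev = float(x0), float(v0)
    for i in range(k):
        v_i = v_prev + w[i]
        y_i = u[i] + max(0.0, v_i - x_prev)
        x_i = x_prev + y_i
        y[i], v[i], x[i] = y_i, v_i, x_i
        omega[i] = x_i - v_i
        x_prev, v_prev = x_i, v_i
    return QueueTrajectory(y=y, v=v, x=x, u=u, omega=omega)


def _draw_uw(params: MG1Params, k: int, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    u = rng.uniform(params.theta1, params.theta2, size=k)
    w = rng.exponential(1.0 / params.theta3, size=k)
    return u, w


def mg1_simulate(params: MG1Params, n: int, n_future: int, rng: np.random.Generator
                 ) -> QueueTrajectory:
    """Simulate customers 1..n+n_future from an empty queue."""
    u, w = _draw_uw(params, n + n_future, rng)
    return mg1_recursion(u, w)


def mg1_conditional_predict(params: MG1Params, x_n: float, v_n: float, n_future: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Future waiting times omega_{n+1..n+n_future} given queue state (x_n, v_n)."""
    if n_future < 1:
        raise ValueError("need at least one future customer")
    if x_n < 0 or v_n < 0:
        raise ValueError("inconsistent queue state")
    u, w = _draw_uw(params, n_future, rng)
    return mg1_recursion(u, w, x0=x_n, v0=v_n).omega


class MG1Model(SimulatorModel):
    """Queue simulator; theta = (theta1, theta2, theta3) on the natural scale.

    The prediction target is the vector of waiting times of the next
    ``n_future`` customers. The stored latent is (x_n, v_n) -- for ABC-L
    the departure part x_n is recomputed from the *observed*
    interdeparture times while v_n comes from the accepted simulation.
    """

    capabilities = frozenset({Capability.JOINT, Capability.JOINT_LATENT,
                              Capability.LATENT_COND_PRED})

    def __init__(self, n: int, n_future: int = 10):
        self.n = int(n)
        self.n_future = int(n_future)

    def simulate_obs(self, theta: np.ndarray, rng: np.random.Generator) -> Simulation:
        params = MG1Params.from_vector(theta)
        u, w = _draw_uw(params, self.n, rng)
        traj = mg1_recursion(u, w)
        return Simulation(y=traj.y, v=np.array([traj.v[-1]]),
                          state=(traj.x[-1], traj.v[-1]))

    def predict_given_state(self, theta: np.ndarray, state: object,
                            rng: np.random.Generator) -> np.ndarray:
        x_n, v_n = state
        return mg1_conditional_predict(MG1Params.from_vector(theta), x_n, v_n,
                                       self.n_future, rng)

    def latent_cond_predict(self, theta: np.ndarray, y_obs: np.ndarray, v: object,
                            rng: np.random.Generator) -> np.ndarray:
        x_n = float(np.sum(y_obs))
        v_n = float(np.atleast_1d(v)[-1])
        return mg1_conditional_predict(MG1Params.from_vector(theta), x_n, v_n,
                                       self.n_future, rng)


def mg1_summaries(y: np.ndarray, variant: str,
                  y_obs_ref: np.ndarray | None = None) -> np.ndarray:
    """Baseline s0 (quantiles + min/max) or extended s1 (s0 + last-exceedance indices).

    The s1 thresholds q_{0.7/0.8/0.9} are computed once from the observed
    data ``y_obs_ref``, not from the trajectory being summarized.
    Empirical quantiles use linear (type-7) interpolation.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty trajectory")
    s0 = np.concatenate([np.quantile(y, [0.25, 0.5, 0.75]),
                         [np.min(y), np.max(y)]])
    if variant == "s0":
        return s0
    if variant != "s1":
        raise ValueError(f"unknown summary variant {variant!r}")
    if y_obs_ref is None:
        raise ValueError("s1 needs the observed data to fix its thresholds")
    thresholds = np.quantile(np.asarray(y_obs_ref, dtype=float), [0.7, 0.8, 0.9])
    idx = np.empty(3)
    for j, q in enumerate(thresholds):
        hits = np.nonzero(y >= q)[0]
        idx[j] = hits[-1] + 1 if hits.size else 1  # max over empty set is 1
    return np.concatenate([s0, idx])


def mg1_summary_spec(variant: str, y_obs_ref: np.ndarray | None = None) -> SummarySpec:
    """SummarySpec for s0 (unpartitioned, d=5) or s1 (partitioned 5 | 3)."""
    if variant == "s0":
        return SummarySpec(fn=lambda y: mg1_summaries(y, "s0"), dim=5)
    ref = np.asarray(y_obs_ref, dtype=float)
    return SummarySpec(fn=lambda y: mg1_summaries(y, "s1", ref), dim=8, dim_bar=5)


class MG1Prior(Prior):
    """(theta1, theta2 - theta1, theta3) ~ U([0,10]^2 x [0, 1/3]), truncated.

    The truncation theta1 <= min(y_obs) encodes the support constraint that
    is implicit in the (intractable) likelihood: no interdeparture time can
    be smaller than the minimum service time. Sampling is by rejection
    against the truncation.
    """

    dim = 3

    def __init__(self, y_obs: np.ndarray):
        y_obs = np.asarray(y_obs, dtype=float)
        self.y_min = float(np.min(y_obs))
        if self.y_min <= 0:
            raise ValueError("observed interdeparture times must be positive")
        # normalizing constant of the truncated box (theta1 cap may be inactive)
        cap = min(self.y_min, 10.0)
        self._lognorm = math.log(cap / 10.0) + math.log(10.0 * 10.0 / 3.0)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        while True:
            t1 = rng.uniform(0.0, 10.0)
            if t1 > self.y_min:
                continue
            gap = rng.uniform(0.0, 10.0)
            t3 = rng.uniform(0.0, 1.0 / 3.0)
            return np.array([t1, t1 + gap, t3])

    def logpdf(self, x: np.ndarray) -> float:
        t1, t2, t3 = np.atleast_1d(np.asarray(x, dtype=float))
        gap = t2 - t1
        if not (0.0 <= t1 <= 10.0 and 0.0 <= gap <= 10.0 and 0.0 <= t3 <= 1.0 / 3.0):
            return -np.inf
        if t1 > self.y_min:
            return -np.inf
        return -self._lognorm
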