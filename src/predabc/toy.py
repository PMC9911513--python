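"""Two-state Bernoulli toy model with a brute-force enumeration oracle.

theta in {0, 1} with a uniform prior; given theta, the pseudo-observation
z and the predicted value ytilde are independent Bernoulli(0.2 + 0.6 *
theta) draws; the summary is z itself. The entire joint law of
(theta, z, ytilde) has eight outcomes, so the joint-predictive ABC target
(acceptance on z against the observed s_y with threshold h) can be
enumerated exactly and used as an oracle for the rejection, importance and
MCMC samplers. The data are i.i.d. given theta, so the two-stage and
joint-simulation predictive targets coincide here.
"""

from __future__ import annotations

import numpy as np

from .core import Capability, Prior, Simulation, SimulatorModel, SummarySpec

__all__ = ["ToyModel", "ToyPrior", "BiasedToyProposal", "toy_summary_spec",
           "enumerate_abc_p_joint"]


def _p_success(theta: float) -> float:
    return 0.2 + 0.6 * (theta >= 0.5)


class ToyModel(SimulatorModel):
    """z, ytilde | theta i.i.d. Bernoulli(0.2 + 0.6 theta); theta in {0, 1}."""

    capabilities = frozenset({Capability.JOINT, Capability.COND_PRED})

    def simulate_obs(self, theta: np.ndarray, rng: np.random.Generator) -> Simulation:
        p = _p_success(float(np.atleast_1d(theta)[0]))
        z = float(rng.random() < p)
        return Simulation(y=np.array([z]), state=None)

    def predict_given_state(self, theta: np.ndarray, state: object,
                            rng: np.random.Generator) -> np.ndarray:
        p = _p_success(float(np.atleast_1d(theta)[0]))
        return np.array([float(rng.random() < p)])

    def cond_predict(self, theta: np.ndarray, y_obs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        # i.i.d. data: pi(ytilde | y, theta) = pi(ytilde | theta)
        return self.predict_given_state(theta, None, rng)


class ToyPrior(Prior):
    """Uniform prior on the two-point set {0, 1}."""

    dim = 1

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([float(rng.integers(0, 2))])

    def logpdf(self, x: np.ndarray) -> float:
        t = float(np.atleast_1d(x)[0])
        return np.log(0.5) if t in (0.0, 1.0) else -np.inf


class BiasedToyProposal:
    """Non-uniform two-point proposal, for importance-weight checks."""

    def __init__(self, p_one: float = 0.8):
        if not 0 < p_one < 1:
            raise ValueError("p_one must be in (0, 1)")
        self.p_one = p_one

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([float(rng.random() < self.p_one)])

    def logpdf(self, x: np.ndarray) -> float:
        t = float(np.atleast_1d(x)[0])
        if t not in (0.0, 1.0):
            return -np.inf
        return float(np.log(self.p_one if t == 1.0 else 1.0 - self.p_one))


def toy_summary_spec() -> SummarySpec:
    return SummarySpec(fn=lambda y: np.atleast_1d(y), dim=1)


def enumerate_abc_p_joint(s_y: float, h: float) -> dict[tuple[int, int], float]:
    """Exact joint-predictive ABC law of (theta, ytilde) by full enumeration.

    Sums the prior x simulator probabilities of all eight outcomes of
    (theta, z, ytilde), keeping those with |z - s_y| <= h, and normalizes.
    Independent of any sampling code path.
    """
    mass: dict[tuple[int, int], float] = {}
    total = 0.0
    for theta in (0, 1):
        p = _p_success(theta)
        for z in (0, 1):
            pz = p if z == 1 else 1.0 - p
            if abs(z - s_y) > h:
                continue
            for yt in (0, 1):
                py = p if yt == 1 else 1.0 - p
                w = 0.5 * pz * py
                mass[(theta, yt)] = mass.get((theta, yt), 0.0) + w
                total += w
    return {k: v / total for k, v in mass.items()}
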