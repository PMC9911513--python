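"""ABC samplers for parameter and posterior-predictive inference.

Three prediction modes are supported on top of the standard ABC posterior:

* ``"posterior"`` -- parameter inference only (no prediction),
* ``"P"``  -- joint simulation of (z, ytilde) | theta; acceptance on s(z)
  targets the augmented predictive distribution,
* ``"L"``  -- joint simulation of (z, v) | theta with a final prediction
  step ytilde ~ pi(ytilde | y, v, theta) run only for retained draws.

ABC-F is the classical two-stage route: standard ABC for theta followed by
direct simulation from pi(ytilde | y, theta) (``abc_f_predict``).

All samplers draw their randomness from deterministic child streams of a
single integer seed. The stream simulating (theta, z) is separate from the
stream simulating predictions, so the theta marginal of a predictive run
is sample-path identical to a plain posterior run with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    Capability,
    Prior,
    ProductKernelRule,
    SimulatorModel,
    SingleKernelRule,
    SummarySpec,
    WeightedSampleSet,
    ZeroAcceptanceError,
    normalize_and_ess,
)

__all__ = [
    "MCMCConfig",
    "GaussianProposal",
    "abc_rejection",
    "abc_importance",
    "abc_mcmc",
    "abc_f_predict",
    "deferred_prediction",
]

# sub-stream tags for deterministic child seeds
_OBS, _PRED, _CHAIN, _INIT_THETA, _INIT_OBS, _INIT_PRED = 0, 1, 2, 3, 4, 5

_MODE_CAPS = {
    "posterior": (Capability.JOINT,),
    "P": (Capability.JOINT,),
    "L": (Capability.JOINT_LATENT, Capability.LATENT_COND_PRED),
}


def _check_mode(model: SimulatorModel, mode: str) -> None:
    if mode not in _MODE_CAPS:
        raise ValueError(f"unknown prediction mode {mode!r}")
    missing = [c for c in _MODE_CAPS[mode] if c not in model.capabilities]
    if missing:
        raise ValueError(
            f"mode {mode!r} requires capabilities {[c.name for c in missing]} "
            f"that {type(model).__name__} does not declare")


def _rng(seed: int, stream: int, i: int | None = None) -> np.random.Generator:
    key = (seed, stream) if i is None else (seed, stream, i)
    return np.random.default_rng(np.random.SeedSequence(key))


def _zero_acceptance(discrepancies: np.ndarray, what: str) -> ZeroAcceptanceError:
    d = np.sort(np.asarray(discrepancies, dtype=float))[:10]
    return ZeroAcceptanceError(
        f"{what}: no draw was accepted; smallest discrepancies seen: {d}",
        smallest_discrepancies=d)


class GaussianProposal:
    """Independent Gaussian proposal density for importance sampling."""

    def __init__(self, mean: Sequence[float], scale: Sequence[float]):
        self.mean = np.atleast_1d(np.asarray(mean, dtype=float))
        self.scale = np.broadcast_to(np.asarray(scale, dtype=float), self.mean.shape)
        if np.any(self.scale <= 0):
            raise ValueError("proposal scales must be positive")

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.scale)

    def logpdf(self, x: np.ndarray) -> float:
        z = (np.atleast_1d(x) - self.mean) / self.scale
        return float(-0.5 * np.sum(z * z) - np.sum(np.log(self.scale))
                     - 0.5 * len(self.mean) * math.log(2 * math.pi))


def _predict_joint(model: SimulatorModel, theta: np.ndarray, sim,
                   rng_pred: np.random.Generator) -> np.ndarray:
    """ytilde drawn jointly with the accepted z (path-embedded or from state)."""
    if sim.ytilde is not None:
        return sim.ytilde
    return model.predict_given_state(theta, sim.state, rng_pred)


def abc_rejection(model: SimulatorModel, prior: Prior, summary: SummarySpec,
                  rule, y_obs: np.ndarray, m: int, seed: int,
                  mode: str = "posterior", store_states: bool = False,
                  ) -> WeightedSampleSet:
    """ABC rejection sampler: draw theta from the prior, simulate, accept on s(z).

    Requires a 0/1 acceptance rule (uniform or product kernel). Accepted
    draws are i.i.d. from the mode's ABC target; in mode "P" each accepted
    record carries the ytilde simulated jointly with its accepted z; in
    mode "L" the prediction step runs only for accepted draws.
    """
    _check_mode(model, mode)
    s_y = summary(y_obs)
    thetas, preds, latents, states, discs = [], [], [], [], []
    all_discs = np.empty(m)
    for i in range(m):
        rng_obs = _rng(seed, _OBS, i)
        theta = prior.sample(rng_obs)
        sim = model.simulate_obs(theta, rng_obs)
        s_z = summary(sim.y)
        d = rule.discrepancies(s_y, s_z)
        all_discs[i] = d[0]
        w = rule.weight(s_y, s_z)
        if w not in (0.0, 1.0):
            raise ValueError("rejection sampling needs a 0/1 acceptance rule "
                             "(uniform or product kernel)")
        if w == 0.0:
            continue
        thetas.append(theta)
        discs.append(d[0])
        if mode == "P":
            preds.append(_predict_joint(model, theta, sim, _rng(seed, _PRED, i)))
        elif mode == "L":
            latents.append(sim.v)
            preds.append(model.latent_cond_predict(theta, y_obs, sim.v,
                                                   _rng(seed, _PRED, i)))
        if store_states:
            states.append(sim.state)
    if not thetas:
        raise _zero_acceptance(all_discs, "ABC rejection")
    k = len(thetas)
    weights, ess = normalize_and_ess(np.ones(k))
    return WeightedSampleSet(
        thetas=np.asarray(thetas), weights=weights,
        discrepancies=np.asarray(discs),
        ytilde=np.asarray(preds) if preds else None,
        v=latents or None, states=states or None,
        acceptance_rate=k / m, ess=ess,
        meta={"sampler": "rejection", "mode": mode, "m": m, "seed": seed})


def abc_importance(model: SimulatorModel, prior: Prior, proposal, summary: SummarySpec,
                   rule, y_obs: np.ndarray, m: int, seed: int,
                   mode: str = "posterior", store_states: bool = False,
                   ) -> WeightedSampleSet:
    """Self-normalized importance sampler for the ABC target.

    The unnormalized weight of draw i is K_h(Delta_i) * pi(theta_i) / q(theta_i):
    the intractable simulator density cancels between target and proposal, so
    the weight depends on the simulation only through the discrepancy. With
    ``proposal = prior`` and a uniform kernel this reduces to rejection
    sampling. Predictions (modes "P"/"L") are simulated only for draws with
    positive weight (two-stage form).
    """
    _check_mode(model, mode)
    s_y = summary(y_obs)
    p = prior.dim
    thetas = np.empty((m, p))
    raw_w = np.empty(m)
    discs = np.empty(m)
    sims = [None] * m
    for i in range(m):
        rng_obs = _rng(seed, _OBS, i)
        theta = np.atleast_1d(proposal.sample(rng_obs))
        sim = model.simulate_obs(theta, rng_obs)
        s_z = summary(sim.y)
        d = rule.discrepancies(s_y, s_z)
        kw = rule.weight(s_y, s_z)
        lp = prior.logpdf(theta)
        thetas[i] = theta
        discs[i] = d[0]
        raw_w[i] = 0.0 if (kw == 0.0 or lp == -np.inf) \
            else kw * math.exp(lp - proposal.logpdf(theta))
        if raw_w[i] > 0 and mode in ("P", "L"):
            sims[i] = sim
    try:
        weights, ess = normalize_and_ess(raw_w)
    except ZeroAcceptanceError:
        raise _zero_acceptance(discs, "ABC importance sampling") from None
    preds = None
    latents = None
    states = [s.state if s is not None else None for s in sims] if store_states else None
    if mode in ("P", "L"):
        preds = [None] * m
        latents = [None] * m
        for i in range(m):
            if sims[i] is None:
                continue
            rng_pred = _rng(seed, _PRED, i)
            if mode == "P":
                preds[i] = _predict_joint(model, thetas[i], sims[i], rng_pred)
            else:
                latents[i] = sims[i].v
                preds[i] = model.latent_cond_predict(thetas[i], y_obs,
                                                     sims[i].v, rng_pred)
        shape = next(np.shape(x) for x in preds if x is not None)
        preds = np.asarray([np.full(shape, np.nan) if x is None else x for x in preds])
    return WeightedSampleSet(
        thetas=thetas, weights=weights, discrepancies=discs,
        ytilde=preds, v=latents, states=states,
        acceptance_rate=float(np.mean(raw_w > 0)), ess=ess,
        meta={"sampler": "importance", "mode": mode, "m": m, "seed": seed})


@dataclass
class MCMCConfig:
    """Configuration of the random-walk ABC-MCMC sampler.

    ``proposal_scale`` is the per-coordinate random-walk standard deviation
    on the inference scale. With ``adapt_scale`` the scale follows a
    Robbins-Monro recursion toward ``target_rate`` during burn-in only and
    is frozen afterwards, so the stationary acceptance ratio is honored
    exactly. ``init`` provides a starting parameter; otherwise up to
    ``init_budget`` prior draws are tried to find a state with positive
    kernel value.
    """

    iterations: int
    burn_in: int = 0
    proposal_scale: float | Sequence[float] = 1.0
    thin: int = 1
    target_rate: float = 0.1
    adapt_scale: bool = False
    init: np.ndarray | None = None
    init_retries: int = 1000   # fresh-simulation retries of the supplied init
    init_budget: int = 100_000
    store_states: bool = False
    max_stored: int = 100_000
    propose: Callable | None = None  # custom proposal: (theta, rng) -> theta*
    log_q_ratio: Callable | None = None  # (theta, theta*) -> log q(theta|theta*)/q(theta*|theta)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if np.any(np.asarray(self.proposal_scale, dtype=float) <= 0):
            raise ValueError("proposal scales must be positive")


def abc_mcmc(model: SimulatorModel, prior: Prior, summary: SummarySpec,
             rule, y_obs: np.ndarray, config: MCMCConfig, seed: int,
             mode: str = "posterior") -> WeightedSampleSet:
    """ABC-MCMC targeting the (augmented) ABC posterior.

    The Metropolis-Hastings ratio is K_h(Delta*) pi(theta*) q(theta|theta*)
    over K_h(Delta) pi(theta) q(theta*|theta); it does not involve ytilde,
    so in mode "P" the prediction is simulated only when a proposal is
    accepted, and the whole record (theta, z-state, ytilde) is repeated on
    rejection. Returns equal-weight, correlated post-burn-in draws (thinned
    to at most ``max_stored`` records).
    """
    _check_mode(model, mode)
    s_y = summary(y_obs)
    rng_chain = _rng(seed, _CHAIN)
    scale = np.asarray(config.proposal_scale, dtype=float)

    # --- initialization: need K_h(Delta(s_y, s_z0)) * pi(theta0) > 0.
    # A supplied init is retried with fresh simulations (the kernel check is
    # stochastic) before falling back to prior search.
    theta, sim, kern_w, disc = None, None, 0.0, np.nan
    init_trials = 0
    if config.init is not None:
        init_arr = np.atleast_1d(np.asarray(config.init, dtype=float))
        cand = [init_arr] * config.init_retries
    else:
        cand = []
    while kern_w <= 0.0:
        init_trials += 1
        if init_trials > config.init_budget:
            raise RuntimeError(
                f"no valid MCMC initial state found within {config.init_budget} "
                "trials; increase the threshold or supply init")
        th = cand.pop() if cand else prior.sample(_rng(seed, _INIT_THETA, init_trials))
        if prior.logpdf(th) == -np.inf:
            continue
        s = model.simulate_obs(th, _rng(seed, _INIT_OBS, init_trials))
        s_z0 = summary(s.y)
        kw = rule.weight(s_y, s_z0)
        if kw > 0.0:
            theta, sim, kern_w = th, s, kw
            disc = rule.discrepancies(s_y, s_z0)[0]

    log_prior = prior.logpdf(theta)
    ytilde = None
    if mode == "P":
        ytilde = _predict_joint(model, theta, sim, _rng(seed, _INIT_PRED, 0))

    n_keep = config.iterations - config.burn_in
    thin = max(config.thin, math.ceil(n_keep / config.max_stored))
    n_stored = n_keep // thin

    p = len(theta)
    thetas = np.empty((n_stored, p))
    discs = np.empty(n_stored)
    preds = [None] * n_stored if mode == "P" else None
    latents = [None] * n_stored if mode == "L" else None
    states = [None] * n_stored if config.store_states else None
    accepted_post = 0
    stored = 0
    # Robbins-Monro on log-scale, standard decay
    rm_step = 1.0

    for it in range(config.iterations):
        if config.propose is not None:
            theta_star = config.propose(theta, rng_chain)
        else:
            theta_star = theta + scale * rng_chain.standard_normal(p)
        lp_star = prior.logpdf(theta_star)
        accept = False
        if lp_star > -np.inf:
            sim_star = model.simulate_obs(theta_star, _rng(seed, _OBS, it))
            s_star = summary(sim_star.y)
            kw_star = rule.weight(s_y, s_star)
            if kw_star > 0.0:
                log_ratio = (math.log(kw_star) - math.log(kern_w)
                             + lp_star - log_prior)
                if config.log_q_ratio is not None:
                    log_ratio += config.log_q_ratio(theta, theta_star)
                accept = log_ratio >= 0 or rng_chain.random() < math.exp(log_ratio)
        if accept:
            theta, sim, kern_w, log_prior = theta_star, sim_star, kw_star, lp_star
            disc = rule.discrepancies(s_y, s_star)[0]
            if mode == "P":
                ytilde = _predict_joint(model, theta, sim, _rng(seed, _PRED, it))
        if it >= config.burn_in:
            if accept:
                accepted_post += 1
            if (it - config.burn_in) % thin == 0 and stored < n_stored:
                thetas[stored] = theta
                discs[stored] = disc
                if mode == "P":
                    preds[stored] = ytilde
                elif mode == "L":
                    latents[stored] = sim.v
                if config.store_states:
                    states[stored] = sim.state
                stored += 1
        elif config.adapt_scale:
            rm_step = 1.0 / (1 + it) ** 0.6
            scale = scale * math.exp(rm_step * ((1.0 if accept else 0.0)
                                                - config.target_rate))

    thetas, discs = thetas[:stored], discs[:stored]
    if mode == "P":
        preds = np.asarray(preds[:stored])
    if mode == "L":
        latents = latents[:stored]
    if config.store_states:
        states = states[:stored]
    weights, ess = normalize_and_ess(np.ones(stored))
    return WeightedSampleSet(
        thetas=thetas, weights=weights, discrepancies=discs,
        ytilde=preds if mode == "P" else None,
        v=latents if mode == "L" else None,
        states=states if config.store_states else None,
        acceptance_rate=accepted_post / max(n_keep, 1), ess=ess,
        meta={"sampler": "mcmc", "mode": mode, "iterations": config.iterations,
              "burn_in": config.burn_in, "thin": thin, "seed": seed,
              "proposal_scale": np.asarray(scale).tolist(),
              "init_trials": init_trials})


def abc_f_predict(theta_samples: WeightedSampleSet, model: SimulatorModel,
                  y_obs: np.ndarray, seed: int) -> WeightedSampleSet:
    """ABC-F: one ytilde ~ pi(ytilde | theta_i, y) per parameter draw.

    Weights are inherited from the parameter sample, so the weighted
    predictive sample targets the two-stage approximation that plugs the
    ABC posterior into the exact conditional predictive.
    """
    if Capability.COND_PRED not in model.capabilities:
        raise ValueError(
            f"{type(model).__name__} cannot sample pi(ytilde | y, theta); "
            "ABC-F needs the COND_PRED capability")
    if len(theta_samples) == 0:
        raise ValueError("empty parameter sample")
    preds = [model.cond_predict(theta_samples.thetas[i], y_obs, _rng(seed, _PRED, i))
             for i in range(len(theta_samples))]
    return WeightedSampleSet(
        thetas=theta_samples.thetas, weights=theta_samples.weights.copy(),
        discrepancies=theta_samples.discrepancies.copy(),
        ytilde=np.asarray(preds),
        acceptance_rate=theta_samples.acceptance_rate, ess=theta_samples.ess,
        meta={**theta_samples.meta, "prediction": "abc_f", "pred_seed": seed})


def deferred_prediction(run: WeightedSampleSet, model: SimulatorModel,
                        which: Sequence[int], seed: int,
                        y_obs: np.ndarray | None = None,
                        use: str = "state") -> np.ndarray:
    """Simulate predictions after the fact for selected records of a run.

    ``use="state"`` draws ytilde ~ pi(ytilde | z_i, v_i, theta_i) from the
    stored simulation state (the latent-variable shortcut for ABC-P: the
    acceptance ratio never involves ytilde, so simulating it only for
    retained records leaves the predictive law unchanged).
    ``use="latent"`` draws ytilde ~ pi(ytilde | y, v_i, theta_i) (the ABC-L
    prediction step; requires ``y_obs`` and stored latents).
    """
    which = np.asarray(list(which), dtype=int)
    if which.size == 0:
        return np.empty((0,))
    if np.any(which < 0) or np.any(which >= len(run)):
        raise IndexError("requested indices outside the stored run")
    out = []
    if use == "state":
        if run.states is None:
            raise ValueError("run does not store simulation states")
        for i in which:
            out.append(model.predict_given_state(run.thetas[i], run.states[i],
                                                 _rng(seed, _PRED, int(i))))
    elif use == "latent":
        if run.v is None:
            raise ValueError("run does not store latent variables")
        if y_obs is None:
            raise ValueError("latent-conditional prediction needs y_obs")
        for i in which:
            out.append(model.latent_cond_predict(run.thetas[i], y_obs, run.v[i],
                                                 _rng(seed, _PRED, int(i))))
    else:
        raise ValueError(f"unknown deferred-prediction source {use!r}")
    return np.asarray(out)
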