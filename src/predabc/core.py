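"""Core types and primitives shared by all ABC predictive samplers.

This module holds the vocabulary of likelihood-free inference: priors,
simulator capability contracts, summary statistics, acceptance kernels,
discrepancies (weighted quadratic forms and the sup norm), pilot-based
weight estimation, threshold calibration, and importance-weight plumbing
(normalization and effective sample size).
"""

from __future__ import annotations

import logging
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from enum import Enum, auto
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Capability",
    "ParameterVector",
    "Prior",
    "UniformBoxPrior",
    "Simulation",
    "SimulatorModel",
    "SummarySpec",
    "KernelSpec",
    "DiscrepancySpec",
    "ProductKernelRule",
    "SingleKernelRule",
    "WeightedSampleSet",
    "ZeroAcceptanceError",
    "evaluate_kernel",
    "compute_discrepancy",
    "product_kernel_accept",
    "estimate_summary_weights",
    "calibrate_threshold",
    "calibrate_product_threshold",
    "normalize_and_ess",
]


class Capability(Enum):
    """Which conditional laws of a simulator can be sampled.

    JOINT            : (y, ytilde) | theta
    JOINT_LATENT     : (y, v, ytilde) | theta
    COND_PRED        : ytilde | y, theta        (needed by ABC-F)
    LATENT_COND_PRED : ytilde | y, v, theta     (needed by ABC-L)
    """

    JOINT = auto()
    JOINT_LATENT = auto()
    COND_PRED = auto()
    LATENT_COND_PRED = auto()


@dataclass
class ParameterVector:
    """Named parameter vector with per-coordinate log-scale flags.

    Coordinates flagged ``log_scale`` are strictly positive on the natural
    scale and are handled on the log scale by samplers (random walks,
    priors on log-coordinates).
    """

    values: np.ndarray
    names: tuple[str, ...]
    log_scale: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.log_scale is None:
            self.log_scale = tuple(False for _ in self.names)
        if len(self.values) != len(self.names) or len(self.names) != len(self.log_scale):
            raise ValueError("values, names and log_scale must have equal length")
        for val, flag, name in zip(self.values, self.log_scale, self.names):
            if flag and val <= 0:
                raise ValueError(f"log-scale coordinate {name!r} must be positive")

    def inference_values(self) -> np.ndarray:
        """Values on the inference scale (log where flagged)."""
        out = self.values.copy()
        for i, flag in enumerate(self.log_scale):
            if flag:
                out[i] = math.log(out[i])
        return out


class Prior(ABC):
    """Prior over the *inference-scale* parameter vector.

    ``logpdf`` is -inf exactly outside the support; ``sample`` always
    returns points inside the support.
    """

    dim: int

    @abstractmethod
    def sample(self, rng: np.random.Generator) -> np.ndarray: ...

    @abstractmethod
    def logpdf(self, x: np.ndarray) -> float: ...


class UniformBoxPrior(Prior):
    """Uniform prior on a box, with optional extra support constraints.

    ``constraints`` is a list of callables x -> bool; the sampler rejects
    box draws violating any of them and the log-density is -inf there.
    """

    def __init__(self, lo: Sequence[float], hi: Sequence[float],
                 constraints: Sequence[Callable[[np.ndarray], bool]] = ()) -> None:
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        if self.lo.shape != self.hi.shape or np.any(self.hi <= self.lo):
            raise ValueError("invalid box bounds")
        self.dim = len(self.lo)
        self.constraints = tuple(constraints)
        self._logvol = -float(np.sum(np.log(self.hi - self.lo)))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        for _ in range(100_000):
            x = rng.uniform(self.lo, self.hi)
            if all(c(x) for c in self.constraints):
                return x
        raise RuntimeError("prior rejection sampler failed: constraints too tight")

    def logpdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.lo) or np.any(x > self.hi):
            return -np.inf
        if not all(c(x) for c in self.constraints):
            return -np.inf
        return self._logvol


@dataclass
class Simulation:
    """One forward simulation: observed-shaped data plus optional extras.

    ``y``      simulated data playing the role of the observations
    ``v``      latent variables (None when the model has none)
    ``state``  whatever ``predict_given_state`` needs to continue the
               process (e.g. last state of a Markov chain)
    ``ytilde`` prediction embedded in the same simulated path (used by
               models where the predicted quantity is part of one path,
               e.g. missing-data reconstruction)
    ``flags``  diagnostics such as trajectory capping
    """

    y: np.ndarray
    v: np.ndarray | None = None
    state: object = None
    ytilde: np.ndarray | None = None
    flags: dict = field(default_factory=dict)


class SimulatorModel(ABC):
    """Capability contract for simulator-based models.

    Concrete models implement ``simulate_obs`` and whichever conditional
    laws they support; ``capabilities`` declares the supported set and is
    validated by the samplers against the requested prediction mode.
    """

    capabilities: frozenset[Capability] = frozenset()

    @abstractmethod
    def simulate_obs(self, theta: np.ndarray, rng: np.random.Generator) -> Simulation:
        """Draw z ~ pi(y[, v] | theta). ``theta`` is on the inference scale."""

    def predict_given_state(self, theta: np.ndarray, state: object,
                            rng: np.random.Generator) -> np.ndarray:
        """Draw ytilde ~ pi(ytilde | z, v, theta) from a stored simulation state."""
        raise NotImplementedError(
            f"{type(self).__name__} does not support prediction from a stored state")

    def simulate_joint(self, theta: np.ndarray, rng_obs: np.random.Generator,
                       rng_pred: np.random.Generator | None,
                       want_pred: bool = True) -> Simulation:
        """Draw (z[, v], ytilde) | theta.

        The observed-data stream ``rng_obs`` is consumed identically
        whether or not a prediction is requested, so the theta/z sample
        path of a run is unchanged by switching prediction on or off.
        """
        sim = self.simulate_obs(theta, rng_obs)
        if want_pred and sim.ytilde is None:
            sim.ytilde = self.predict_given_state(theta, sim.state, rng_pred)
        return sim

    def cond_predict(self, theta: np.ndarray, y_obs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        """Draw ytilde ~ pi(ytilde | y, theta) (ABC-F). Optional capability."""
        raise NotImplementedError(
            f"{type(self).__name__} cannot sample the conditional predictive "
            "pi(ytilde | y, theta); ABC-F is unavailable for this model")

    def latent_cond_predict(self, theta: np.ndarray, y_obs: np.ndarray, v: object,
                            rng: np.random.Generator) -> np.ndarray:
        """Draw ytilde ~ pi(ytilde | y, v, theta) (ABC-L). Optional capability."""
        raise NotImplementedError(
            f"{type(self).__name__} cannot sample the latent conditional predictive "
            "pi(ytilde | y, v, theta); ABC-L is unavailable for this model")


@dataclass
class SummarySpec:
    """Map from a data trajectory to a real vector, optionally partitioned.

    ``dim_bar``/``dim_tilde`` split the output into a parameter-informative
    block s_bar (first ``dim_bar`` coordinates) and a prediction-informative
    block s_tilde; ``dim_bar + dim_tilde == dim``. An unpartitioned summary
    has ``dim_tilde == 0``.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    dim: int
    dim_bar: int | None = None

    def __post_init__(self) -> None:
        if self.dim_bar is None:
            self.dim_bar = self.dim
        if not 0 <= self.dim_bar <= self.dim:
            raise ValueError("block dimensions must sum to the summary dimension")

    @property
    def dim_tilde(self) -> int:
        return self.dim - self.dim_bar

    def __call__(self, y: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.fn(y), dtype=float))
        if s.shape != (self.dim,):
            raise ValueError(f"summary returned shape {s.shape}, expected ({self.dim},)")
        return s

    def split(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return s[: self.dim_bar], s[self.dim_bar:]


@dataclass
class KernelSpec:
    """Acceptance kernel: uniform indicator or Gaussian, bandwidth h >= 0.

    ``h = inf`` with the uniform kernel accepts everything.
    """

    kind: str  # "uniform" | "gaussian"
    h: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.h < 0:
            raise ValueError("bandwidth must be nonnegative")


def evaluate_kernel(kernel: KernelSpec, r: float) -> float:
    """K_h(r) in [0, 1] for a nonnegative discrepancy value r."""
    if r < 0:
        raise ValueError("discrepancy must be nonnegative")
    if math.isinf(kernel.h):
        return 1.0
    if kernel.kind == "uniform":
        return 1.0 if r <= kernel.h else 0.0
    # gaussian
    if kernel.h == 0:
        return 1.0 if r == 0 else 0.0
    return math.exp(-(r * r) / (2.0 * kernel.h * kernel.h))


@dataclass
class DiscrepancySpec:
    """Norm-like discrepancy between two summary vectors.

    kind "quadratic": r^T P r with P a precision matrix, or sum_i w_i r_i^2
    with a nonnegative weight vector (both live on the *squared* scale, so
    thresholds calibrated against this discrepancy are squared-scale too).
    kind "linf": max_i |r_i|.

    ``provenance`` records how the weights were obtained (e.g. "pilot-cov",
    "pilot-mad", "identity").
    """

    kind: str  # "quadratic" | "linf"
    weights: np.ndarray | None = None  # vector or precision matrix for "quadratic"
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.kind not in ("quadratic", "linf"):
            raise ValueError(f"unknown discrepancy kind {self.kind!r}")
        if self.kind == "quadratic":
            if self.weights is None:
                raise ValueError("quadratic discrepancy needs weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.ndim == 1:
                if np.any(self.weights < 0):
                    raise ValueError("weight vector must be nonnegative")
            elif self.weights.ndim == 2:
                # positive definiteness check via Cholesky
                try:
                    np.linalg.cholesky(self.weights)
                except np.linalg.LinAlgError as exc:
                    raise ValueError("precision matrix must be positive definite") from exc
            else:
                raise ValueError("weights must be a vector or a matrix")

    @classmethod
    def identity(cls, dim: int) -> "DiscrepancySpec":
        return cls("quadratic", np.ones(dim), provenance="identity")

    @classmethod
    def linf(cls) -> "DiscrepancySpec":
        return cls("linf")


def compute_discrepancy(spec: DiscrepancySpec, s_a: np.ndarray, s_b: np.ndarray) -> float:
    """Delta(s_a, s_b): symmetric, zero iff s_a == s_b for PD weights."""
    s_a = np.atleast_1d(np.asarray(s_a, dtype=float))
    s_b = np.atleast_1d(np.asarray(s_b, dtype=float))
    if s_a.shape != s_b.shape:
        raise ValueError(f"summary dimension mismatch: {s_a.shape} vs {s_b.shape}")
    r = s_a - s_b
    if spec.kind == "linf":
        return float(np.max(np.abs(r))) if r.size else 0.0
    w = spec.weights
    if w.ndim == 1:
        if w.shape != r.shape:
            raise ValueError("weight vector dimension mismatch")
        return float(np.sum(w * r * r))
    if w.shape[0] != r.size:
        raise ValueError("precision matrix dimension mismatch")
    return float(r @ w @ r)


@dataclass
class SingleKernelRule:
    """Acceptance weight from one discrepancy and one kernel."""

    discrepancy: DiscrepancySpec
    kernel: KernelSpec

    def discrepancies(self, s_y: np.ndarray, s_z: np.ndarray) -> tuple[float, ...]:
        return (compute_discrepancy(self.discrepancy, s_y, s_z),)

    def weight(self, s_y: np.ndarray, s_z: np.ndarray) -> float:
        return evaluate_kernel(self.kernel, self.discrepancies(s_y, s_z)[0])


@dataclass
class ProductKernelRule:
    """Product of two uniform kernels on the (s_bar, s_tilde) blocks.

    Accepts iff  ||s_bar_y - s_bar_z|| <= h_bar  and
                 ||s_tilde_y - s_tilde_z||' <= h_tilde.
    With an empty s_tilde block this reduces to the single uniform kernel
    on the s_bar block.
    """

    partition: SummarySpec
    norm_bar: DiscrepancySpec
    norm_tilde: DiscrepancySpec
    h_bar: float
    h_tilde: float

    def __post_init__(self) -> None:
        if self.h_bar < 0 or self.h_tilde < 0:
            raise ValueError("thresholds must be nonnegative")

    def discrepancies(self, s_y: np.ndarray, s_z: np.ndarray) -> tuple[float, ...]:
        by, ty = self.partition.split(np.asarray(s_y, dtype=float))
        bz, tz = self.partition.split(np.asarray(s_z, dtype=float))
        d_bar = compute_discrepancy(self.norm_bar, by, bz)
        d_tilde = compute_discrepancy(self.norm_tilde, ty, tz) if ty.size else 0.0
        return (d_bar, d_tilde)

    def weight(self, s_y: np.ndarray, s_z: np.ndarray) -> float:
        d_bar, d_tilde = self.discrepancies(s_y, s_z)
        return 1.0 if (d_bar <= self.h_bar and d_tilde <= self.h_tilde) else 0.0


def product_kernel_accept(s_y: np.ndarray, s_z: np.ndarray, partition: SummarySpec,
                          norm_bar: DiscrepancySpec, norm_tilde: DiscrepancySpec,
                          h_bar: float, h_tilde: float) -> int:
    """0/1 product-kernel acceptance of a simulated summary against the observed one."""
    if partition is None:
        raise ValueError("product kernel acceptance requires a partitioned summary")
    rule = ProductKernelRule(partition, norm_bar, norm_tilde, h_bar, h_tilde)
    return int(rule.weight(s_y, s_z))


def estimate_summary_weights(model: SimulatorModel, summary: SummarySpec,
                             theta_ref: np.ndarray, n_pilot: int,
                             method: str, rng: np.random.Generator,
                             ridge: float = 1e-8) -> DiscrepancySpec:
    """Pilot-run weighting of a summary statistic at a reference parameter.

    method "cov": quadratic form with the inverse of the (ridge-regularized)
    empirical covariance of ``n_pilot`` pilot summaries.
    method "mad": diagonal weights 1 / MAD_i^2 (unscaled median absolute
    deviation per coordinate).

    A coordinate with zero pilot variability is an error naming it: such a
    statistic carries no calibration information and would get infinite
    weight.
    """
    if n_pilot < 2:
        raise ValueError("need at least two pilot simulations")
    if method not in ("cov", "mad"):
        raise ValueError(f"unknown weighting method {method!r}")
    sims = np.empty((n_pilot, summary.dim))
    for i in range(n_pilot):
        sims[i] = summary(model.simulate_obs(theta_ref, rng).y)
    return summary_weights_from_pilot(sims, method, ridge=ridge)


def summary_weights_from_pilot(sims: np.ndarray, method: str,
                               ridge: float = 1e-8) -> DiscrepancySpec:
    """Build a quadratic DiscrepancySpec from an (n_pilot, d) pilot-summary table."""
    sims = np.asarray(sims, dtype=float)
    if method == "mad":
        med = np.median(sims, axis=0)
        mad = np.median(np.abs(sims - med), axis=0)
        for j, m in enumerate(mad):
            if m == 0:
                raise ValueError(
                    f"summary coordinate {j} has zero pilot variability (MAD = 0)")
        return DiscrepancySpec("quadratic", 1.0 / mad**2, provenance="pilot-mad")
    cov = np.cov(sims, rowvar=False)
    cov = np.atleast_2d(cov)
    diag = np.diag(cov)
    for j, v in enumerate(diag):
        if v == 0:
            raise ValueError(
                f"summary coordinate {j} has zero pilot variability (variance = 0)")
    cov = cov + ridge * np.diag(diag)
    prec = np.linalg.inv(cov)
    # symmetrize against round-off
    prec = 0.5 * (prec + prec.T)
    return DiscrepancySpec("quadratic", prec, provenance="pilot-cov")


def calibrate_threshold(draws: np.ndarray, rate: float) -> float:
    """Threshold h such that a fraction ``rate`` of the discrepancy draws is accepted.

    Returns the k-th smallest draw with k = floor(rate * len(draws)), at
    least 1, so the realized acceptance rate on the draws is within one
    draw of the target.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot calibrate a threshold from zero discrepancy draws")
    if not 0 < rate <= 1:
        raise ValueError("target acceptance rate must be in (0, 1]")
    k = max(1, int(math.floor(rate * draws.size + 1e-12)))
    return float(np.partition(draws, k - 1)[k - 1])


def calibrate_product_threshold(d_bar: np.ndarray, d_tilde: np.ndarray,
                                h_tilde: float, rate: float,
                                min_conditional: int = 20) -> float:
    """h_bar such that P(d_bar <= h_bar, d_tilde <= h_tilde) ~= rate on the draws.

    The s_tilde threshold is fixed (chosen on the scale of the data); h_bar
    is the conditional quantile of d_bar among draws already passing the
    s_tilde factor. If too few draws pass, the conditioning falls back to
    the ``min_conditional`` draws with the smallest d_tilde.
    """
    d_bar = np.asarray(d_bar, dtype=float)
    d_tilde = np.asarray(d_tilde, dtype=float)
    n = d_bar.size
    mask = d_tilde <= h_tilde
    n_pass = int(mask.sum())
    if n_pass < min_conditional:
        order = np.argsort(d_tilde)[:min_conditional]
        mask = np.zeros(n, dtype=bool)
        mask[order] = True
        n_pass = min_conditional
        logger.warning("only %d/%d pilot draws pass the s_tilde threshold; "
                       "falling back to the %d closest", int((d_tilde <= h_tilde).sum()),
                       n, min_conditional)
    cond_rate = min(1.0, rate * n / n_pass)
    return calibrate_threshold(d_bar[mask], cond_rate)


class ZeroAcceptanceError(RuntimeError):
    """All importance weights are zero / no draw was accepted.

    Carries the smallest discrepancies seen, as a diagnostic for choosing
    a larger threshold.
    """

    def __init__(self, message: str, smallest_discrepancies: np.ndarray | None = None):
        super().__init__(message)
        self.smallest_discrepancies = smallest_discrepancies


def normalize_and_ess(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize nonnegative importance weights; return (weights, ESS = 1/sum w_i^2)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0:
        raise ZeroAcceptanceError("all importance weights are zero")
    w = w / total
    ess = 1.0 / float(np.sum(w * w))
    if ess < 0.01 * w.size:
        logger.warning("effective sample size %.1f is below 1%% of m=%d", ess, w.size)
    return w, ess


@dataclass
class WeightedSampleSet:
    """Weighted draws of (theta[, ytilde[, v]]) with acceptance diagnostics.

    ``weights`` are normalized to sum to one; ``discrepancies`` holds the
    per-draw discrepancy (first block for product kernels); ``meta`` echoes
    seeds and resolved configuration.
    """

    thetas: np.ndarray
    weights: np.ndarray
    discrepancies: np.ndarray
    ytilde: np.ndarray | None = None
    v: list | None = None
    states: list | None = None
    acceptance_rate: float = float("nan")
    ess: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.thetas)
        if len(self.weights) != m or len(self.discrepancies) != m:
            raise ValueError("sample arrays must have equal length")
        if self.ytilde is not None and len(self.ytilde) != m:
            raise ValueError("ytilde length mismatch")

    def __len__(self) -> int:
        return len(self.thetas)
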