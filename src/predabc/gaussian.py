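"""Exact conditioning in Gaussian location models with a flat prior.

The models used for validation (the AR(1) chain and the linear-Gaussian
state-space model) share the structure

    u = c * m + eps,        eps ~ N(0, V),        c ~ flat on R,

where ``u`` stacks every Gaussian quantity of interest (observations,
latent states, future values). Conditioning a linear target

    T = a_c * c + T_mat @ u

on a linear observation

    s = A @ u + h * eta,    eta ~ N(0, I)

and integrating the flat prior on ``c`` analytically gives the exact
posterior (and posterior-predictive) laws used as independent oracles for
the ABC samplers, including kernel-smoothed ("h > 0") variants: a Gaussian
acceptance kernel between summaries is exactly the observation noise term
``h * eta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaussianDensity", "FlatLocationGaussian"]


@dataclass
class GaussianDensity:
    """A univariate Gaussian; variance 0 marks the exact-conditioning degenerate limit."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")

    @property
    def std(self) -> float:
        return float(np.sqrt(self.variance))


class FlatLocationGaussian:
    """u = c*m + eps with eps ~ N(0, V) and a flat (improper) prior on c."""

    def __init__(self, m: np.ndarray, V: np.ndarray):
        self.m = np.asarray(m, dtype=float)
        self.V = np.asarray(V, dtype=float)
        n = len(self.m)
        if self.V.shape != (n, n):
            raise ValueError("mean vector and covariance dimensions disagree")

    def condition(self, A: np.ndarray, s_obs: np.ndarray, h: float = 0.0,
                  T_mat: np.ndarray | None = None,
                  a_c: np.ndarray | float = 0.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and covariance of T = a_c*c + T_mat @ u given s_obs.

        ``A`` is (k, n); the observation is A @ u plus N(0, h^2 I) kernel
        noise. ``T_mat`` is (q, n) (defaults to empty, i.e. target = c when
        a_c = 1). Returns (mean (q,), cov (q, q)).
        """
        A = np.atleast_2d(np.asarray(A, dtype=float))
        s_obs = np.atleast_1d(np.asarray(s_obs, dtype=float))
        if h < 0:
            raise ValueError("kernel bandwidth must be nonnegative")
        if T_mat is None:
            T_mat = np.zeros((np.size(a_c), len(self.m)))
        T_mat = np.atleast_2d(np.asarray(T_mat, dtype=float))
        a_c = np.broadcast_to(np.atleast_1d(np.asarray(a_c, dtype=float)),
                              (T_mat.shape[0],))

        R = A @ self.V @ A.T + (h * h) * np.eye(A.shape[0])
        b = A @ self.m                      # observation loading on c
        Rinv_b = np.linalg.solve(R, b)
        var_c = 1.0 / float(b @ Rinv_b)     # flat-prior posterior variance of c
        c_hat = var_c * float(Rinv_b @ s_obs)

        C = T_mat @ self.V @ A.T            # target-observation covariance given c
        G = np.linalg.solve(R, C.T).T       # gain
        g = a_c + T_mat @ self.m - G @ b    # residual loading of the target on c

        mean = G @ s_obs + g * c_hat
        cov = T_mat @ self.V @ T_mat.T - G @ C.T + var_c * np.outer(g, g)
        return mean, 0.5 * (cov + cov.T)

    def condition_scalar(self, A: np.ndarray, s_obs: np.ndarray, h: float = 0.0,
                         t: np.ndarray | None = None,
                         a_c: float = 0.0) -> GaussianDensity:
        """Scalar-target convenience wrapper around :meth:`condition`."""
        T_mat = None if t is None else np.atleast_2d(t)
        mean, cov = self.condition(A, s_obs, h=h, T_mat=T_mat, a_c=a_c)
        return GaussianDensity(float(mean[0]), max(float(cov[0, 0]), 0.0))
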