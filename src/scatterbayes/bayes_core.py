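"""Priors, likelihood, posterior and regularized cost.

The prior is a truncated multivariate Gaussian: Gaussian density inside
an admissible set M (positive radii, positive material constants,
positive total fields) and zero outside.  The likelihood compares the
observation operator F(nu) with the data d under the Mahalanobis metric
of the noise covariance Gamma_n = sigma_n^2 I.  All normalisation
constants are dropped: only differences of log-densities ever matter for
sampling and MAP search, so

    log p(nu | d) = -1/2 (nu-nu0)' Gpr^-1 (nu-nu0)
                    - 1/(2 sigma_n^2) ||F(nu) - d||^2      (nu in M)

and -inf outside M.  The regularized cost J_R(nu) is the negative of
this log-posterior.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg as sla

from .geometry_params import params_per_inclusion, unpack_params
from .wave_forward import ConfigurationError

__all__ = [
    "PriorSpec",
    "NoiseModel",
    "Posterior",
    "star_prior_cov",
    "elliptic_prior_cov",
    "star_constraint",
    "elliptic_constraint",
    "additive_field_constraint",
    "no_constraint",
]


def no_constraint(nu: np.ndarray) -> bool:
    return True


@dataclass
class PriorSpec:
    """Truncated Gaussian prior N(nu0, Gpr) restricted to the set M.

    ``cov`` may be a 1-D array (diagonal covariance) or a full SPD
    matrix; the Cholesky factorisation is computed once here, so a
    singular covariance fails at construction rather than evaluation.
    ``constraint`` is the indicator of M.
    """

    mean: np.ndarray
    cov: np.ndarray
    constraint: Callable[[np.ndarray], bool] = no_constraint

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.ndim == 1:
            if self.cov.shape[0] != n:
                raise ConfigurationError("diagonal covariance length != mean length")
            if np.any(self.cov <= 0):
                raise ConfigurationError("prior variances must be positive")
            self._chol = None
        elif self.cov.shape == (n, n):
            try:
                self._chol = sla.cho_factor(self.cov, lower=True)
            except sla.LinAlgError as exc:
                raise ConfigurationError(f"prior covariance is not SPD: {exc}") from exc
        else:
            raise ConfigurationError("covariance must be a vector or an N x N matrix")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def log_density(self, nu: np.ndarray) -> float:
        """Unnormalised truncated-Gaussian log-density; -inf outside M."""
        nu = np.asarray(nu, dtype=float).ravel()
        if nu.shape[0] != self.dim:
            raise ConfigurationError(f"parameter vector length {nu.shape[0]} != N={self.dim}")
        if not self.constraint(nu):
            return -np.inf
        r = nu - self.mean
        if self._chol is None:
            return float(-0.5 * np.sum(r**2 / self.cov))
        return float(-0.5 * r @ sla.cho_solve(self._chol, r))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Raw Gaussian draws (not yet restricted to M)."""
        z = rng.standard_normal((size, self.dim))
        if self._chol is None:
            return self.mean + z * np.sqrt(self.cov)
        lower = np.tril(self._chol[0])
        return self.mean + z @ lower.T

    def std(self) -> np.ndarray:
        if self._chol is None:
            return np.sqrt(self.cov)
        return np.sqrt(np.diag(self.cov))


@dataclass
class NoiseModel:
    """Additive Gaussian observation noise with Gamma_n = sigma_n^2 I."""

    sigma: float
    dim: int
    alpha: float | None = None  # percent level the sigma was derived from
    recipe: str | None = None  # "max" or "rms"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("noise sigma must be positive")

    def log_likelihood(self, predicted: np.ndarray, data: np.ndarray) -> float:
        """-||F(nu) - d||^2 / (2 sigma_n^2), constants dropped."""
        r = np.asarray(predicted, dtype=float).ravel() - np.asarray(data, dtype=float).ravel()
        return float(-0.5 * np.dot(r, r) / self.sigma**2)


class Posterior:
    """Unnormalised posterior combining prior, forward model and noise.

    ``forward`` maps a parameter vector to the flattened predicted data
    (dimension D).  Forward evaluations are cached on the byte image of
    nu so accept/reject cycles never recompute a wave solve.
    """

    def __init__(
        self,
        forward: Callable[[np.ndarray], np.ndarray],
        data: np.ndarray,
        noise: NoiseModel,
        prior: PriorSpec,
        cache_size: int = 512,
    ) -> None:
        self.forward = forward
        self.data = np.asarray(data, dtype=float).ravel()
        self.noise = noise
        self.prior = prior
        self._cache: OrderedDict[bytes, float] = OrderedDict()
        self._cache_size = cache_size

    def log_prior(self, nu: np.ndarray) -> float:
        return self.prior.log_density(nu)

    def log_likelihood(self, nu: np.ndarray) -> float:
        nu = np.asarray(nu, dtype=float).ravel()
        key = nu.tobytes()
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        try:
            predicted = self.forward(nu)
        except Exception as exc:
            raise RuntimeError(f"forward model failed at nu={nu!r}") from exc
        val = self.noise.log_likelihood(predicted, self.data)
        self._cache[key] = val
        if len(self._cache) > self._cache_size:
            self._cache.popitem(last=False)
        return val

    def log_posterior(self, nu: np.ndarray) -> float:
        lp = self.log_prior(nu)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(nu)

    def neg_log_like(self, nu: np.ndarray) -> float:
        """Phi(nu) for pCN/FES: the negative log-likelihood, +inf outside M.

        The Gaussian part of the prior is handled by the pCN proposal
        itself; only the constraint-set indicator enters Phi, so
        proposals leaving M are rejected outright.
        """
        if not self.prior.constraint(np.asarray(nu, dtype=float).ravel()):
            return np.inf
        return -self.log_likelihood(nu)

    def cost(self, nu: np.ndarray) -> float:
        """Regularized cost J_R(nu) = -log posterior, for nu in M."""
        lp = self.log_posterior(nu)
        if not np.isfinite(lp):
            raise ConfigurationError("J_R is undefined outside the constraint set M")
        return -lp

    def __call__(self, nu: np.ndarray) -> float:
        return self.log_posterior(nu)


# ----------------------------------------------------------------------
# covariance recipes


def star_prior_cov(
    Q: int,
    s: float = 3.0,
    sigma_materials: tuple[float, ...] = (20.0,),
    n_inclusions: int = 1,
) -> np.ndarray:
    """Diagonal prior variances for star-shaped inclusion blocks.

    Per block: centre variances 0.1, leading radius 0.1, the order-q
    harmonic pair 0.1/(1+q^2)^s (favouring smooth positive radii), and
    one variance sigma_m^2 per material parameter.  The default material
    deviation 20 is deliberately wide so the posterior can reach stiff
    (scar or malignant) values from a soft prior mean.
    """
    if Q < 1:
        raise ConfigurationError("need at least one harmonic (Q >= 1)")
    harmonics = np.repeat(0.1 / (1.0 + np.arange(1, Q + 1) ** 2.0) ** s, 2)
    block = np.concatenate([[0.1, 0.1, 0.1], harmonics, np.square(sigma_materials)])
    return np.tile(block, n_inclusions)


def elliptic_prior_cov(
    rho_range: tuple[float, float],
    vp_range: tuple[float, float],
    n_inclusions: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Prior (variances, means) for elliptic inclusion blocks.

    Geometry entries are diag(1, 1, 0.5, 0.5, 0.1); the material standard
    deviations are half the layer ranges, sigma = (max - min)/2, and the
    material means the mid-range values — a blind choice that carries no
    information on the inclusion's nature.
    """
    rho_min, rho_max = rho_range
    vp_min, vp_max = vp_range
    if rho_max <= rho_min or vp_max <= vp_min:
        raise ConfigurationError("material ranges must be increasing")
    s_rho = 0.5 * (rho_max - rho_min)
    s_vp = 0.5 * (vp_max - vp_min)
    var_block = np.array([1.0, 1.0, 0.5, 0.5, 0.1, s_rho**2, s_vp**2])
    mean_block = np.array(
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.5 * (rho_max + rho_min), 0.5 * (vp_max + vp_min)]
    )
    return np.tile(var_block, n_inclusions), np.tile(mean_block, n_inclusions)


# ----------------------------------------------------------------------
# constraint-set factories (the indicator of M)


def star_constraint(
    mode: str, n_inclusions: int, order: int, n_angles: int = 256
) -> Callable[[np.ndarray], bool]:
    """Indicator of M for star parameterizations.

    Requires r(theta) > 0 on a uniform grid of ``n_angles`` angles and
    strictly positive material parameters; positivity is enforced by
    rejection (zero prior mass outside), never by projection.
    """
    expected = n_inclusions * params_per_inclusion(mode, order)

    def check(nu: np.ndarray) -> bool:
        nu = np.asarray(nu, dtype=float).ravel()
        if nu.shape[0] != expected:
            raise ConfigurationError(f"expected N={expected}, got {nu.shape[0]}")
        incset = unpack_params(
            nu, mode, n_inclusions, order, mu_background=1.0, vp_background=1.0
        )
        return incset.is_valid(n_angles)

    return check


def elliptic_constraint(n_inclusions: int) -> Callable[[np.ndarray], bool]:
    """Positive semi-axes, density and velocity for every ellipse."""

    def check(nu: np.ndarray) -> bool:
        nu = np.asarray(nu, dtype=float).ravel()
        if nu.shape[0] != 7 * n_inclusions:
            raise ConfigurationError(f"expected N={7 * n_inclusions}, got {nu.shape[0]}")
        blocks = nu.reshape(n_inclusions, 7)
        return bool(
            np.all(blocks[:, 2] > 0)
            and np.all(blocks[:, 3] > 0)
            and np.all(blocks[:, 5] > 0)
            and np.all(blocks[:, 6] > 0)
        )

    return check


def additive_field_constraint(
    evaluate: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    background_rho: np.ndarray,
    background_vp: np.ndarray,
) -> Callable[[np.ndarray], bool]:
    """Indicator of M for additive corrector fields: rho > 0 and vp > 0.

    ``evaluate`` maps nu to the (rho_corrector, vp_corrector) arrays on
    the check grid.
    """

    def check(nu: np.ndarray) -> bool:
        rho_c, vp_c = evaluate(np.asarray(nu, dtype=float).ravel())
        return bool(
            np.all(background_rho + rho_c > 0) and np.all(background_vp + vp_c > 0)
        )

    return check
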