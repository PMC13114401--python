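"""Ensemble MCMC samplers: AIES, pCN and the functional ensemble sampler.

Three complementary samplers cover the progression from low- to
high-dimensional posteriors:

* AIES — the affine-invariant ensemble sampler.  W interacting walkers
  are updated by stretch moves: walker j proposes
  X_j' = X_k + z (X_j - X_k) against a complementary walker k, with z
  drawn from g(z) ~ 1/sqrt(z) on [1/a, a], accepted with probability
  min(1, z^(N-1) p(X_j')/p(X_j)).  Affine invariance makes it robust to
  badly scaled targets; it needs W > 2N walkers.

* pCN — the preconditioned Crank-Nicolson proposal
  nu' = sqrt(1-beta^2) nu + beta xi with xi a prior draw.  It is
  reversible with respect to the centred Gaussian prior, so acceptance
  depends on the likelihood alone and does not degenerate as the
  dimension grows.

* FES — a Metropolis-within-Gibbs alternation: AIES stretch moves on the
  E_L dominant (largest prior eigenvalue) coordinates conditional on the
  rest, then one pCN sweep on the remaining coordinates.  With E_L = 0
  the sweep is exactly pCN (bit-for-bit at a fixed seed).

All samplers are seed-deterministic in serial mode, and a proposal
falling outside the constraint set M is rejected (its log-density is
-inf); walkers are never projected back into M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bayes_core import PriorSpec
from .wave_forward import ConfigurationError

__all__ = [
    "ChainRecord",
    "FESConfig",
    "InitializationError",
    "stretch_draw",
    "stretch_log_accept",
    "aies_run",
    "pcn_step",
    "pcn_run",
    "fes_run",
    "init_ensemble",
]


class InitializationError(RuntimeError):
    """The ensemble could not be initialised inside the constraint set."""


def _warn_degenerate_span(walkers: np.ndarray) -> None:
    """Stretch moves explore only the affine span of the ensemble.

    A coordinate with zero spread across walkers can never move; this is
    almost always an initialisation mistake (e.g. all-zero walkers).
    """
    import warnings

    flat_coords = np.nonzero(np.ptp(walkers, axis=0) == 0.0)[0]
    if flat_coords.size:
        warnings.warn(
            f"coordinates {flat_coords.tolist()} have zero spread across the "
            "ensemble; stretch moves cannot explore them — initialise the "
            "walkers from the prior",
            stacklevel=3,
        )


@dataclass
class ChainRecord:
    """Output of an ensemble run.

    ``samples`` has shape (n_stored, W, N) and includes the initial
    ensemble; ``log_posts`` the matching log-densities; ``accepted`` one
    row of booleans per move.  Burn-in is a fraction of the stored steps
    (default 0.2) used by the summary helpers.
    """

    samples: np.ndarray
    log_posts: np.ndarray
    accepted: np.ndarray
    seed: int | None = None
    burn_in_fraction: float = 0.2
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.samples.shape[0] - 1

    @property
    def n_walkers(self) -> int:
        return self.samples.shape[1]

    @property
    def dim(self) -> int:
        return self.samples.shape[2]

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted)) if self.accepted.size else 0.0

    def burn_in_steps(self, burn_in: int | float | None = None) -> int:
        if burn_in is None:
            burn_in = self.burn_in_fraction
        if isinstance(burn_in, float) and 0 <= burn_in < 1:
            return int(burn_in * self.samples.shape[0])
        burn = int(burn_in)
        if burn >= self.samples.shape[0]:
            raise ConfigurationError("burn-in exceeds the chain length")
        return burn

    def flat(self, burn_in: int | float | None = None) -> np.ndarray:
        """Post-burn-in samples flattened over steps and walkers."""
        burn = self.burn_in_steps(burn_in)
        return self.samples[burn:].reshape(-1, self.dim)

    def flat_log_posts(self, burn_in: int | float | None = None) -> np.ndarray:
        burn = self.burn_in_steps(burn_in)
        return self.log_posts[burn:].ravel()

    def map_sample(self) -> tuple[np.ndarray, float]:
        """Stored sample with the highest log-density (earliest tie wins)."""
        idx = int(np.argmax(self.log_posts))
        step, walker = np.unravel_index(idx, self.log_posts.shape)
        return self.samples[step, walker].copy(), float(self.log_posts[step, walker])


@dataclass(frozen=True)
class FESConfig:
    """FES tuning: E_L low modes treated by AIES, pCN step size beta."""

    n_low: int = 8
    beta: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= 1.0):
            raise ConfigurationError("pCN step size beta must lie in (0, 1]")
        if self.n_low < 0:
            raise ConfigurationError("E_L must be non-negative")


# ----------------------------------------------------------------------
# stretch-move primitives


def stretch_draw(u: np.ndarray, a: float = 2.0) -> np.ndarray:
    """Inverse-transform sample of g(z) ~ 1/sqrt(z) on [1/a, a].

    z = ((a-1) u + 1)^2 / a for u ~ U(0, 1).
    """
    u = np.asarray(u, dtype=float)
    return ((a - 1.0) * u + 1.0) ** 2 / a


def stretch_log_accept(z: float, lp_prop: float, lp_cur: float, dim: int) -> float:
    """log of the stretch-move acceptance probability min(1, z^(N-1) ratio)."""
    return min(0.0, (dim - 1) * np.log(z) + lp_prop - lp_cur)


def _eval_logpost(log_post, proposals: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        return np.asarray(log_post(proposals), dtype=float)
    return np.array([log_post(p) for p in proposals], dtype=float)


def aies_run(
    log_post: Callable,
    init: np.ndarray,
    n_steps: int,
    a: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    vectorized: bool = False,
    enforce_ensemble_size: bool = True,
) -> ChainRecord:
    """Affine-invariant ensemble sampling with split-half stretch moves.

    Each step updates the first half of the ensemble against the frozen
    second half and vice versa, which preserves the correct invariant
    distribution while staying parallelisable.  ``vectorized`` marks a
    target that accepts a (batch, N) array.
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    W, N = init.shape
    if enforce_ensemble_size and W <= 2 * N:
        raise ConfigurationError(f"AIES needs W > 2N walkers (got W={W}, N={N})")
    if W < 4:
        raise ConfigurationError("split-half updates need at least 4 walkers")
    if rng is None:
        rng = np.random.default_rng(seed)

    x = init.copy()
    _warn_degenerate_span(x)
    lp = _eval_logpost(log_post, x, vectorized)
    bad = ~np.isfinite(lp)
    if np.any(bad):
        raise InitializationError(
            f"initial walkers {np.nonzero(bad)[0].tolist()} have non-finite log-posterior"
        )

    samples = np.empty((n_steps + 1, W, N))
    log_posts = np.empty((n_steps + 1, W))
    accepted = np.zeros((n_steps, W), dtype=bool)
    samples[0], log_posts[0] = x, lp

    half = W // 2
    groups = (np.arange(half), np.arange(half, W))
    for step in range(n_steps):
        for g in (0, 1):
            active, other = groups[g], groups[1 - g]
            na = active.size
            z = stretch_draw(rng.random(na), a)
            partners = other[rng.integers(0, other.size, size=na)]
            proposals = x[partners] + z[:, None] * (x[active] - x[partners])
            lp_prop = _eval_logpost(log_post, proposals, vectorized)
            log_u = np.log(rng.random(na))
            with np.errstate(invalid="ignore"):
                acc = log_u < (N - 1) * np.log(z) + lp_prop - lp[active]
            acc &= np.isfinite(lp_prop)
            idx = active[acc]
            x[idx] = proposals[acc]
            lp[idx] = lp_prop[acc]
            accepted[step, idx] = True
        samples[step + 1], log_posts[step + 1] = x, lp

    return ChainRecord(
        samples, log_posts, accepted, seed=seed, meta={"sampler": "aies", "a": a}
    )


# ----------------------------------------------------------------------
# pCN and FES


def pcn_step(x: np.ndarray, xi: np.ndarray, beta: float) -> np.ndarray:
    """One pCN proposal nu' = sqrt(1 - beta^2) nu + beta xi."""
    if not (0.0 < beta <= 1.0):
        raise ConfigurationError("pCN step size beta must lie in (0, 1]")
    return np.sqrt(1.0 - beta**2) * x + beta * xi


def _pcn_sweep(
    x: np.ndarray,
    phi_vals: np.ndarray,
    std: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    phi: Callable[[np.ndarray], float],
) -> np.ndarray:
    """In-place pCN sweep over all walkers; returns the accept mask.

    The proposal is prior-reversible, so acceptance uses only the
    negative log-likelihood Phi: accept with prob min(1, e^{Phi - Phi'}).
    """
    W, n = x.shape
    xi = rng.standard_normal((W, n)) * std
    log_u = np.log(rng.random(W))
    proposals = pcn_step(x, xi, beta)
    acc = np.zeros(W, dtype=bool)
    for w in range(W):
        phi_new = phi(proposals[w])
        if log_u[w] < phi_vals[w] - phi_new:
            x[w] = proposals[w]
            phi_vals[w] = phi_new
            acc[w] = True
    return acc


def _gauss_logpdf(x: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Unnormalised centred-Gaussian log prior, per walker."""
    return -0.5 * np.sum((x / std) ** 2, axis=-1)


def pcn_run(
    neg_log_like: Callable[[np.ndarray], float],
    prior_std: np.ndarray,
    init: np.ndarray,
    n_steps: int,
    beta: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ChainRecord:
    """pCN sampling of prior x exp(-Phi) with a centred diagonal prior.

    ``prior_std`` holds the per-coordinate prior standard deviations
    (sqrt of the KL eigenvalues).  The recorded log_posts are the full
    unnormalised log-posterior (Gaussian log prior minus Phi).
    """
    if not (0.0 < beta <= 1.0):
        raise ConfigurationError("pCN step size beta must lie in (0, 1]")
    init = np.atleast_2d(np.asarray(init, dtype=float))
    W, N = init.shape
    std = np.asarray(prior_std, dtype=float).ravel()
    if std.shape[0] != N:
        raise ConfigurationError("prior_std length does not match the state dimension")
    if rng is None:
        rng = np.random.default_rng(seed)

    x = init.copy()
    phi_vals = np.array([neg_log_like(w) for w in x], dtype=float)
    if np.any(~np.isfinite(phi_vals)):
        raise InitializationError("initial walkers have non-finite likelihood")

    samples = np.empty((n_steps + 1, W, N))
    log_posts = np.empty((n_steps + 1, W))
    accepted = np.zeros((n_steps, W), dtype=bool)
    samples[0] = x
    log_posts[0] = _gauss_logpdf(x, std) - phi_vals

    for step in range(n_steps):
        accepted[step] = _pcn_sweep(x, phi_vals, std, beta, rng, neg_log_like)
        samples[step + 1] = x
        log_posts[step + 1] = _gauss_logpdf(x, std) - phi_vals

    return ChainRecord(
        samples, log_posts, accepted, seed=seed, meta={"sampler": "pcn", "beta": beta}
    )


def fes_run(
    neg_log_like: Callable[[np.ndarray], float],
    prior_std: np.ndarray,
    config: FESConfig,
    init: np.ndarray,
    n_steps: int,
    a: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    enforce_ensemble_size: bool = True,
) -> ChainRecord:
    """Functional ensemble sampling over a KL coordinate split.

    Coordinates are assumed ordered by decreasing prior eigenvalue (the
    KLBasis convention); the first ``config.n_low`` are the dominant
    modes.  Each sweep applies split-half AIES stretch moves to the low
    block, with the conditional target

        -1/2 sum_low (x/sigma)^2 - Phi(x_low, x_high fixed),

    then one pCN sweep on the high block.  With n_low = 0 no AIES random
    numbers are drawn and the trajectory is identical to :func:`pcn_run`.

    The ensemble-size requirement W > 2 E_L applies to the AIES block;
    ``enforce_ensemble_size`` additionally checks the stricter published
    initialisation rule W > 4N + 1 when set to "strict".
    """
    init = np.atleast_2d(np.asarray(init, dtype=float))
    W, N = init.shape
    EL = config.n_low
    if EL > N:
        raise ConfigurationError(f"E_L={EL} exceeds the dimension N={N}")
    std = np.asarray(prior_std, dtype=float).ravel()
    if std.shape[0] != N:
        raise ConfigurationError("prior_std length does not match the state dimension")
    if EL > 0:
        if enforce_ensemble_size and W <= 2 * EL:
            raise ConfigurationError(f"FES needs W > 2 E_L walkers (got W={W}, E_L={EL})")
        if enforce_ensemble_size == "strict" and W <= 4 * N + 1:
            raise ConfigurationError(f"strict mode requires W > 4N+1 (got W={W}, N={N})")
        if W < 4:
            raise ConfigurationError("split-half updates need at least 4 walkers")
    if rng is None:
        rng = np.random.default_rng(seed)

    x = init.copy()
    if EL > 0:
        _warn_degenerate_span(x[:, :EL])
    phi_vals = np.array([neg_log_like(w) for w in x], dtype=float)
    if np.any(~np.isfinite(phi_vals)):
        raise InitializationError("initial walkers have non-finite likelihood")

    samples = np.empty((n_steps + 1, W, N))
    log_posts = np.empty((n_steps + 1, W))
    accepted_low = np.zeros((n_steps, W), dtype=bool)
    accepted_high = np.zeros((n_steps, W), dtype=bool)
    samples[0] = x
    log_posts[0] = _gauss_logpdf(x, std) - phi_vals

    std_low, std_high = std[:EL], std[EL:]
    half = W // 2
    groups = (np.arange(half), np.arange(half, W))

    for step in range(n_steps):
        if EL > 0:
            # conditional log target on the low block, per walker
            cond = _gauss_logpdf(x[:, :EL], std_low) - phi_vals
            for g in (0, 1):
                active, other = groups[g], groups[1 - g]
                na = active.size
                z = stretch_draw(rng.random(na), a)
                partners = other[rng.integers(0, other.size, size=na)]
                prop_low = x[partners][:, :EL] + z[:, None] * (
                    x[active][:, :EL] - x[partners][:, :EL]
                )
                log_u = np.log(rng.random(na))
                for i, wk in enumerate(active):
                    trial = x[wk].copy()
                    trial[:EL] = prop_low[i]
                    phi_new = neg_log_like(trial)
                    lp_new = _gauss_logpdf(trial[:EL], std_low) - phi_new
                    if np.isfinite(lp_new) and log_u[i] < (EL - 1) * np.log(z[i]) + lp_new - cond[wk]:
                        x[wk] = trial
                        phi_vals[wk] = phi_new
                        cond[wk] = lp_new
                        accepted_low[step, wk] = True
        if EL < N:
            # pCN on the high block; draw order mirrors _pcn_sweep exactly
            # so that E_L = 0 reproduces pcn_run bit for bit
            x_high = x[:, EL:].copy()
            xi = rng.standard_normal((W, N - EL)) * std_high
            log_u = np.log(rng.random(W))
            proposals = pcn_step(x_high, xi, config.beta)
            for w in range(W):
                trial = x[w].copy()
                trial[EL:] = proposals[w]
                phi_new = neg_log_like(trial)
                if log_u[w] < phi_vals[w] - phi_new:
                    x[w] = trial
                    phi_vals[w] = phi_new
                    accepted_high[step, w] = True
        samples[step + 1] = x
        log_posts[step + 1] = _gauss_logpdf(x, std) - phi_vals

    accepted = accepted_low | accepted_high if EL > 0 else accepted_high
    return ChainRecord(
        samples,
        log_posts,
        accepted,
        seed=seed,
        meta={
            "sampler": "fes",
            "n_low": EL,
            "beta": config.beta,
            "a": a,
            "accept_low": float(np.mean(accepted_low)) if EL > 0 else None,
            "accept_high": float(np.mean(accepted_high)) if EL < N else None,
        },
    )


# ----------------------------------------------------------------------
# initialisation


def init_ensemble(
    prior: PriorSpec,
    n_walkers: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 100,
) -> np.ndarray:
    """Draw W prior samples, rejection-resampled into the constraint set.

    Raises :class:`InitializationError` with diagnostics if ``max_tries``
    batches of W draws do not yield enough admissible walkers (a sign the
    prior puts almost no mass inside M).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    n_drawn = 0
    for _ in range(max_tries):
        batch = prior.sample(rng, n_walkers)
        n_drawn += n_walkers
        for row in batch:
            if prior.constraint(row):
                keep.append(row)
                if len(keep) == n_walkers:
                    return np.asarray(keep)
    raise InitializationError(
        f"only {len(keep)} of {n_walkers} walkers found inside M after "
        f"{n_drawn} prior draws; the prior may be inconsistent with the constraints"
    )
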