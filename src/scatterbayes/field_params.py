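"""High-dimensional corrector-field parameterizations.

When the number and shape of anomalies is unknown, the density and
velocity are written as known background profiles plus corrector fields,

    rho = rho0 + rho_c,    vp = vp0 + vp_c,

and the correctors are expanded in a finite basis whose coefficients are
the random variables of the Bayesian problem.  Two bases are provided:

* a truncated double Fourier expansion on the box [0,Lx] x [0,Ly] with a
  diagonal prior whose mode-(q,r) variance decays as sigma0^2/(1+q^2+r^2)^s;
* a truncated Karhunen-Loeve (KL) expansion of a Gaussian random field
  with Matern-type covariance (tau^2 I - Laplacian)^(-delta), realised
  through the explicit Dirichlet eigenpairs of the shifted Laplacian on
  the box.

A lognormal variant expands the log-fields instead, which guarantees
positivity unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wave_forward import ConfigurationError, MediumFields

__all__ = [
    "BackgroundFields",
    "fourier_n_coeffs",
    "fourier_eval",
    "fourier_project",
    "fourier_prior_cov",
    "MaternSpec",
    "helmholtz_eigenvalues",
    "helmholtz_eigenfunction",
    "matern_cov_eigs",
    "KLBasis",
    "kl_sample",
    "kl_eval",
    "total_fields",
    "lognormal_match",
]


@dataclass
class BackgroundFields:
    """Known background profiles rho0 and vp0 on the inversion grid."""

    rho0: np.ndarray
    vp0: np.ndarray

    def __post_init__(self) -> None:
        self.rho0 = np.asarray(self.rho0, dtype=float)
        self.vp0 = np.asarray(self.vp0, dtype=float)
        if self.rho0.shape != self.vp0.shape:
            raise ConfigurationError("background fields must share a shape")
        if np.any(self.rho0 <= 0) or np.any(self.vp0 <= 0):
            raise ConfigurationError("background fields must be strictly positive")


# ----------------------------------------------------------------------
# Fourier parameterization


def fourier_n_coeffs(Nx: int, Ny: int) -> int:
    """Coefficients per field: 1 + 2Nx + 2Ny + 4 Nx Ny."""
    return 1 + 2 * Nx + 2 * Ny + 4 * Nx * Ny


def _fourier_design(points: np.ndarray, Nx: int, Ny: int, Lx: float, Ly: float) -> np.ndarray:
    """Design matrix whose columns follow the relabelled coefficient order.

    Order: A00, A_{q,0}, B_{q,0}, A_{0,r}, B_{0,r}, then the doubly
    indexed families A_{q,r}, B_{q,r}, C_{q,r}, D_{q,r}, each q-major.
    Weights: the constant term enters as A00/4, single-index terms as
    coefficient/2, double-index terms with weight 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = pts[:, 0], pts[:, 1]
    q = np.arange(1, Nx + 1)
    r = np.arange(1, Ny + 1)
    cx = np.cos(2 * np.pi * np.outer(x, q) / Lx)  # (n, Nx)
    sx = np.sin(2 * np.pi * np.outer(x, q) / Lx)
    cy = np.cos(2 * np.pi * np.outer(y, r) / Ly)  # (n, Ny)
    sy = np.sin(2 * np.pi * np.outer(y, r) / Ly)
    n = pts.shape[0]
    cols = [np.full((n, 1), 0.25), 0.5 * cx, 0.5 * sx, 0.5 * cy, 0.5 * sy]
    # double-index blocks, q-major: columns (q-1)*Ny + (r-1)
    cols.append((cx[:, :, None] * cy[:, None, :]).reshape(n, Nx * Ny))
    cols.append((sx[:, :, None] * sy[:, None, :]).reshape(n, Nx * Ny))
    cols.append((cx[:, :, None] * sy[:, None, :]).reshape(n, Nx * Ny))
    cols.append((sx[:, :, None] * cy[:, None, :]).reshape(n, Nx * Ny))
    return np.concatenate(cols, axis=1)


def fourier_eval(
    coeffs: np.ndarray, points: np.ndarray, Nx: int, Ny: int, Lx: float, Ly: float
) -> np.ndarray:
    """Evaluate the truncated Fourier corrector at arbitrary points."""
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    if coeffs.shape[0] != fourier_n_coeffs(Nx, Ny):
        raise ConfigurationError(
            f"expected {fourier_n_coeffs(Nx, Ny)} coefficients, got {coeffs.shape[0]}"
        )
    return _fourier_design(points, Nx, Ny, Lx, Ly) @ coeffs


def fourier_project(
    values: np.ndarray, points: np.ndarray, Nx: int, Ny: int, Lx: float, Ly: float
) -> np.ndarray:
    """Least-squares projection of sampled field values onto the basis.

    Exact (up to round-off) whenever the sampled field lies in the
    truncated span and the point set resolves all retained modes.
    """
    design = _fourier_design(points, Nx, Ny, Lx, Ly)
    if design.shape[0] < design.shape[1]:
        raise ConfigurationError(
            f"{design.shape[0]} sample points cannot determine {design.shape[1]} coefficients"
        )
    sol, *_ = np.linalg.lstsq(design, np.asarray(values, dtype=float).ravel(), rcond=None)
    return sol


def fourier_prior_cov(Nx: int, Ny: int, sigma0: float, s: float) -> np.ndarray:
    """Diagonal prior variances sigma0^2/(1+q^2+r^2)^s per coefficient.

    Requires s > 1 so the variances are summable and the random series
    converges in L2.  The returned vector follows the coefficient order
    of :func:`fourier_eval`.
    """
    if s <= 1.0:
        raise ConfigurationError("need s > 1 for a summable Fourier prior")
    q = np.arange(1, Nx + 1, dtype=float)
    r = np.arange(1, Ny + 1, dtype=float)
    vx = sigma0**2 / (1.0 + q**2) ** s
    vy = sigma0**2 / (1.0 + r**2) ** s
    vqr = (sigma0**2 / (1.0 + q[:, None] ** 2 + r[None, :] ** 2) ** s).ravel()
    return np.concatenate([[sigma0**2], vx, vx, vy, vy, vqr, vqr, vqr, vqr])


# ----------------------------------------------------------------------
# KL machinery


@dataclass(frozen=True)
class MaternSpec:
    """Matern-type covariance (tau^2 I - Laplacian)^(-delta).

    tau = 1/l is the inverse correlation length, gamma controls sample
    roughness (gamma = 1/2 is the exponential kernel), n is the spatial
    dimension and delta = gamma + n/2.  Covariance eigenvalues are
    lambda_i = mu_i^(-s) from the shifted-Laplacian eigenvalues mu_i;
    the default follows s = delta/2, with ``exponent="full"`` exposing
    the alternative s = delta reading.
    """

    tau: float
    gamma: float = 0.5
    n: int = 2
    sigma2: float = 1.0
    exponent: str = "half"  # "half": s = delta/2, "full": s = delta

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.gamma <= 0:
            raise ConfigurationError("need tau > 0 and gamma > 0")
        if self.exponent not in ("half", "full"):
            raise ConfigurationError("exponent must be 'half' or 'full'")

    @property
    def delta(self) -> float:
        return self.gamma + self.n / 2.0

    @property
    def s(self) -> float:
        return self.delta / 2.0 if self.exponent == "half" else self.delta

    @property
    def correlation_length(self) -> float:
        return 1.0 / self.tau


def helmholtz_eigenvalues(Nx: int, Ny: int, tau: float, Lx: float, Ly: float) -> np.ndarray:
    """Dirichlet eigenvalues mu_{q,r} = tau^2 + pi^2 (q^2/Lx^2 + r^2/Ly^2).

    Shape (Nx, Ny), indices q = 1..Nx, r = 1..Ny.
    """
    q = np.arange(1, Nx + 1, dtype=float)
    r = np.arange(1, Ny + 1, dtype=float)
    return tau**2 + np.pi**2 * (np.add.outer(q**2 / Lx**2, r**2 / Ly**2))


def helmholtz_eigenfunction(q: int, r: int, points: np.ndarray, Lx: float, Ly: float) -> np.ndarray:
    """L2-normalised Dirichlet sine eigenfunction on [0,Lx] x [0,Ly]."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    norm = np.sqrt(4.0 / (Lx * Ly))
    return norm * np.sin(np.pi * q * pts[:, 0] / Lx) * np.sin(np.pi * r * pts[:, 1] / Ly)


def matern_cov_eigs(spec: MaternSpec, mu: np.ndarray) -> np.ndarray:
    """Covariance eigenvalues sigma2 * mu^(-s), sorted non-increasing."""
    mu = np.asarray(mu, dtype=float).ravel()
    if np.any(mu <= 0):
        raise ConfigurationError("Helmholtz eigenvalues must be positive")
    lam = spec.sigma2 * mu ** (-spec.s)
    return np.sort(lam, kind="stable")[::-1]


@dataclass
class KLBasis:
    """Truncated KL basis on a tensor grid over [0,Lx] x [0,Ly].

    ``eigenvalues`` are sorted non-increasing (ties broken by (q,r)
    lexicographic order); ``basis`` is the matrix P whose rows are the
    discretised eigenfunctions at the grid points, so that a field draw
    is P.T @ xi and the discrete covariance is C = P.T diag(lambda) P.
    """

    Lx: float
    Ly: float
    spec: MaternSpec
    index_map: np.ndarray  # (N, 2) the (q, r) of each retained mode
    eigenvalues: np.ndarray  # (N,) covariance eigenvalues, descending
    helmholtz: np.ndarray  # (N,) corresponding mu_{q,r}
    points: np.ndarray  # (n_points, 2)
    basis: np.ndarray = field(repr=False)  # (N, n_points)

    @classmethod
    def build(
        cls,
        Nx: int,
        Ny: int,
        spec: MaternSpec,
        points: np.ndarray,
        Lx: float,
        Ly: float,
    ) -> "KLBasis":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        mu_grid = helmholtz_eigenvalues(Nx, Ny, spec.tau, Lx, Ly)
        qr = np.array([(q, r) for q in range(1, Nx + 1) for r in range(1, Ny + 1)])
        mu = mu_grid.ravel()
        lam = spec.sigma2 * mu ** (-spec.s)
        # descending eigenvalue, ties by (q, r) lexicographic
        order = np.lexsort((qr[:, 1], qr[:, 0], -lam))
        qr, mu, lam = qr[order], mu[order], lam[order]
        P = np.stack(
            [helmholtz_eigenfunction(q, r, pts, Lx, Ly) for q, r in qr], axis=0
        )
        return cls(Lx, Ly, spec, qr, lam, mu, pts, P)

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def covariance(self) -> np.ndarray:
        """Discretised covariance matrix C = P.T diag(lambda) P."""
        return (self.basis.T * self.eigenvalues) @ self.basis

    def index_of(self, q: int, r: int) -> int:
        """Flat index ell of mode (q, r): bijective by construction."""
        hits = np.nonzero((self.index_map[:, 0] == q) & (self.index_map[:, 1] == r))[0]
        if hits.size != 1:
            raise ConfigurationError(f"mode ({q}, {r}) not in the basis")
        return int(hits[0])


def kl_sample(basis: KLBasis, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Independent KL coefficients xi_ell ~ N(0, lambda_ell)."""
    std = np.sqrt(basis.eigenvalues)
    if size is None:
        return rng.standard_normal(basis.n_modes) * std
    return rng.standard_normal((size, basis.n_modes)) * std


def kl_eval(nu: np.ndarray, basis: KLBasis, points: np.ndarray | None = None) -> np.ndarray:
    """Corrector field sum_ell nu_ell phi_ell, linear in nu.

    Evaluates on the basis grid unless other ``points`` are supplied.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape[-1] != basis.n_modes:
        raise ConfigurationError(
            f"expected {basis.n_modes} KL coefficients, got {nu.shape[-1]}"
        )
    if points is None:
        P = basis.basis
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        P = np.stack(
            [
                helmholtz_eigenfunction(q, r, pts, basis.Lx, basis.Ly)
                for q, r in basis.index_map
            ],
            axis=0,
        )
    return nu @ P


# ----------------------------------------------------------------------
# combining background and correctors


@dataclass
class TotalFields:
    """Nodewise rho, vp (and mu = rho vp^2) with an admissibility flag.

    ``admissible`` is False when the additive mode produced non-positive
    density or velocity somewhere; values are never clipped — the flag
    feeds the constraint set of the prior.
    """

    rho: np.ndarray
    vp: np.ndarray
    admissible: bool

    @property
    def mu(self) -> np.ndarray:
        return self.rho * self.vp**2

    def as_medium(self) -> MediumFields:
        if not self.admissible:
            raise ConfigurationError("fields are outside the admissible set")
        return MediumFields.from_velocity(self.rho, self.vp)


def total_fields(
    background: BackgroundFields,
    rho_corr: np.ndarray,
    vp_corr: np.ndarray,
    mode: str = "additive",
) -> TotalFields:
    """Combine background and correctors.

    additive:  rho = rho0 + rho_c (positivity is a constraint, flagged);
    lognormal: rho = exp(log rho0 + rho_c), always positive.
    """
    rho_corr = np.asarray(rho_corr, dtype=float)
    vp_corr = np.asarray(vp_corr, dtype=float)
    if rho_corr.shape != background.rho0.shape or vp_corr.shape != background.vp0.shape:
        raise ConfigurationError("corrector shapes do not match the background")
    if mode == "additive":
        rho = background.rho0 + rho_corr
        vp = background.vp0 + vp_corr
        ok = bool(np.all(rho > 0) and np.all(vp > 0))
        return TotalFields(rho, vp, ok)
    if mode == "lognormal":
        rho = np.exp(np.log(background.rho0) + rho_corr)
        vp = np.exp(np.log(background.vp0) + vp_corr)
        return TotalFields(rho, vp, True)
    raise ConfigurationError(f"unknown field mode {mode!r}")


def lognormal_match(mu0: float, sigma0: float) -> tuple[float, float]:
    """Gaussian (mu, sigma^2) of the log matching lognormal moments.

    Inverts mean mu0 = exp(mu + sigma^2/2) and variance
    sigma0 = exp(2 mu + sigma^2)(exp(sigma^2) - 1):

        sigma^2 = log(sigma0 / mu0^2 + 1),   mu = log(mu0) - sigma^2/2.
    """
    if mu0 <= 0 or sigma0 <= 0:
        raise ConfigurationError("lognormal matching needs mu0 > 0 and sigma0 > 0")
    sigma2 = float(np.log(sigma0 / mu0**2 + 1.0))
    mu = float(np.log(mu0) - 0.5 * sigma2)
    return mu, sigma2
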