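"""Low-dimensional inclusion parameterizations.

Anomalies are modelled as star-shaped regions whose radius is a truncated
trigonometric series of the normalised angle theta in [0, 1],

    r(theta) = a0 + 2 sum_q [ c_q cos(2 pi q theta) + s_q sin(2 pi q theta) ],

or as rotated ellipses.  Each inclusion carries constant material values:
in tissue mode a shear modulus only (density is uniform), in geophysics
mode a density and a longitudinal velocity.  A set of inclusions plus a
background rasterises to piecewise-constant medium fields on a mesh.

Parameter-vector layout (per inclusion, concatenated over inclusions):

    tissue   (2Q+4): cx, cy, a0, s_1, c_1, ..., s_Q, c_Q, mu
    star     (2Q+5): cx, cy, a0, s_1, c_1, ..., s_Q, c_Q, rho, vp
    elliptic (7):    cx, cy, ax, ay, angle, rho, vp
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wave_forward import ConfigurationError, MediumFields, Mesh

__all__ = [
    "StarInclusion",
    "EllipticInclusion",
    "InclusionSet",
    "star_radius",
    "star_contour",
    "contains",
    "rasterize_fields",
    "pack_params",
    "unpack_params",
    "params_per_inclusion",
]

MODES = ("tissue", "star", "elliptic")


def params_per_inclusion(mode: str, Q: int = 0) -> int:
    """Length of one inclusion's parameter block for a given mode."""
    if mode == "tissue":
        return 2 * Q + 4
    if mode == "star":
        return 2 * Q + 5
    if mode == "elliptic":
        return 7
    raise ConfigurationError(f"unknown parameterization mode {mode!r}")


@dataclass
class StarInclusion:
    """Star-shaped inclusion with trigonometric radius of order Q."""

    center: np.ndarray  # (2,)
    radius0: float  # leading radius coefficient a0
    sin_coeffs: np.ndarray  # (Q,)
    cos_coeffs: np.ndarray  # (Q,)
    mu: float | None = None  # tissue mode
    rho: float | None = None  # geophysics mode
    vp: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.sin_coeffs = np.atleast_1d(np.asarray(self.sin_coeffs, dtype=float))
        self.cos_coeffs = np.atleast_1d(np.asarray(self.cos_coeffs, dtype=float))
        if self.sin_coeffs.shape != self.cos_coeffs.shape:
            raise ConfigurationError("sin and cos coefficient counts differ")

    @property
    def order(self) -> int:
        return self.sin_coeffs.shape[0]

    def radius(self, theta) -> np.ndarray:
        return star_radius(self, theta)

    def is_valid(self, n_angles: int = 256) -> bool:
        """Positive radius on a uniform angle grid, positive materials."""
        theta = np.arange(n_angles) / n_angles
        if np.any(self.radius(theta) <= 0.0):
            return False
        mats = [m for m in (self.mu, self.rho, self.vp) if m is not None]
        return all(m > 0.0 for m in mats)


@dataclass
class EllipticInclusion:
    """Rotated ellipse with centre, semi-axes, tilt and materials."""

    center: np.ndarray
    semi_axes: np.ndarray  # (ax, ay)
    angle: float  # tilt of the x semi-axis, radians
    rho: float = 1.0
    vp: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(2)

    def is_valid(self, n_angles: int = 256) -> bool:
        return bool(np.all(self.semi_axes > 0) and self.rho > 0 and self.vp > 0)


@dataclass
class InclusionSet:
    """Ordered inclusions over a constant background medium.

    The background is given as (rho, mu) in tissue mode or (rho, vp) in
    geophysics modes.  Overlaps are resolved by letting the last-listed
    inclusion win, which is immaterial for the intended well-separated
    configurations but keeps rasterisation deterministic.
    """

    inclusions: list = field(default_factory=list)
    mode: str = "tissue"
    rho_background: float = 1.0
    mu_background: float | None = None
    vp_background: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        # an empty set is allowed and rasterises to the pure background

    @property
    def n_inclusions(self) -> int:
        return len(self.inclusions)

    @property
    def order(self) -> int:
        inc = self.inclusions[0]
        return inc.order if isinstance(inc, StarInclusion) else 0

    def is_valid(self, n_angles: int = 256) -> bool:
        return all(inc.is_valid(n_angles) for inc in self.inclusions)


# ----------------------------------------------------------------------
# geometry


def star_radius(inclusion: StarInclusion, theta):
    """Radius r(theta) of the trigonometric expansion; theta in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    q = np.arange(1, inclusion.order + 1)
    ang = 2.0 * np.pi * np.multiply.outer(theta, q)
    r = (
        inclusion.radius0
        + 2.0 * (np.cos(ang) * inclusion.cos_coeffs).sum(axis=-1)
        + 2.0 * (np.sin(ang) * inclusion.sin_coeffs).sum(axis=-1)
    )
    return r if r.ndim else float(r)


def star_contour(inclusion: StarInclusion, theta):
    """Contour point q(theta) = center + r(theta) (cos 2 pi theta, sin 2 pi theta)."""
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(star_radius(inclusion, theta))
    direction = np.stack([np.cos(2 * np.pi * theta), np.sin(2 * np.pi * theta)], axis=-1)
    return inclusion.center + r[..., None] * direction


def contains(inclusion, points) -> np.ndarray:
    """Membership test for star or elliptic inclusions.

    A point is inside a star inclusion when its distance to the centre is
    below r(theta_p), with theta_p the polar angle fraction of the point;
    the centre itself counts as inside.  Ellipses use the rotated-ellipse
    inequality.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - inclusion.center if isinstance(inclusion, StarInclusion) else pts - inclusion.center
    if isinstance(inclusion, StarInclusion):
        dist = np.hypot(rel[:, 0], rel[:, 1])
        theta = np.arctan2(rel[:, 1], rel[:, 0]) / (2 * np.pi) % 1.0
        inside = dist < np.asarray(star_radius(inclusion, theta))
        inside[dist == 0.0] = True
    elif isinstance(inclusion, EllipticInclusion):
        ca, sa = np.cos(inclusion.angle), np.sin(inclusion.angle)
        xr = ca * rel[:, 0] + sa * rel[:, 1]
        yr = -sa * rel[:, 0] + ca * rel[:, 1]
        ax, ay = inclusion.semi_axes
        inside = (xr / ax) ** 2 + (yr / ay) ** 2 < 1.0
    else:
        raise ConfigurationError(f"unsupported inclusion type {type(inclusion)!r}")
    return inside if np.asarray(points).ndim > 1 else bool(inside[0])


# ----------------------------------------------------------------------
# rasterisation


def rasterize_fields(
    incset: InclusionSet,
    mesh: Mesh,
    background: MediumFields | None = None,
) -> MediumFields:
    """Piecewise-constant medium fields from an inclusion set.

    Each element takes the value of the inclusion containing its centroid
    (last-listed inclusion wins on overlap), and the background value
    elsewhere.  A non-constant background (e.g. a layered medium) can be
    supplied as ready-made ``MediumFields``.
    """
    centroids = mesh.element_centroids()
    n = mesh.n_elements
    if background is not None:
        rho = background.rho.copy()
        mu = background.mu.copy()
    elif incset.mode == "tissue":
        if incset.mu_background is None:
            raise ConfigurationError("tissue mode needs a background shear modulus")
        rho = np.full(n, incset.rho_background)
        mu = np.full(n, incset.mu_background)
    else:
        if incset.vp_background is None:
            raise ConfigurationError("geophysics modes need a background velocity")
        rho = np.full(n, incset.rho_background)
        mu = rho * incset.vp_background**2

    for inc in incset.inclusions:
        mask = contains(inc, centroids)
        if incset.mode == "tissue":
            if inc.mu is None or inc.mu <= 0:
                raise ConfigurationError("tissue inclusion needs a positive shear modulus")
            mu[mask] = inc.mu
        else:
            if inc.rho is None or inc.vp is None or inc.rho <= 0 or inc.vp <= 0:
                raise ConfigurationError("inclusion needs positive density and velocity")
            rho[mask] = inc.rho
            mu[mask] = inc.rho * inc.vp**2
    return MediumFields(rho, mu)


# ----------------------------------------------------------------------
# packing


def _pack_star(inc: StarInclusion, mode: str) -> np.ndarray:
    pairs = np.column_stack([inc.sin_coeffs, inc.cos_coeffs]).ravel()
    head = np.concatenate([inc.center, [inc.radius0], pairs])
    if mode == "tissue":
        return np.concatenate([head, [inc.mu]])
    return np.concatenate([head, [inc.rho, inc.vp]])


def pack_params(incset: InclusionSet) -> np.ndarray:
    """Concatenate all inclusion blocks into one parameter vector nu."""
    blocks = []
    for inc in incset.inclusions:
        if incset.mode == "elliptic":
            blocks.append(
                np.concatenate([inc.center, inc.semi_axes, [inc.angle, inc.rho, inc.vp]])
            )
        else:
            blocks.append(_pack_star(inc, incset.mode))
    return np.concatenate(blocks)


def unpack_params(
    nu: np.ndarray,
    mode: str,
    n_inclusions: int,
    order: int = 0,
    *,
    rho_background: float = 1.0,
    mu_background: float | None = None,
    vp_background: float | None = None,
) -> InclusionSet:
    """Inverse of :func:`pack_params`; validates the vector length."""
    nu = np.asarray(nu, dtype=float).ravel()
    per = params_per_inclusion(mode, order)
    expect = n_inclusions * per
    if nu.shape[0] != expect:
        raise ConfigurationError(
            f"parameter vector has length {nu.shape[0]}, expected N={expect} "
            f"for mode={mode!r}, L={n_inclusions}, Q={order}"
        )
    incs = []
    for ell in range(n_inclusions):
        b = nu[ell * per : (ell + 1) * per]
        if mode == "elliptic":
            incs.append(EllipticInclusion(b[0:2], b[2:4], b[4], rho=b[5], vp=b[6]))
        else:
            pairs = b[3 : 3 + 2 * order].reshape(order, 2) if order else np.zeros((0, 2))
            kwargs = {"mu": b[-1]} if mode == "tissue" else {"rho": b[-2], "vp": b[-1]}
            incs.append(
                StarInclusion(b[0:2], b[2], pairs[:, 0], pairs[:, 1], **kwargs)
            )
    return InclusionSet(
        incs,
        mode=mode,
        rho_background=rho_background,
        mu_background=mu_background,
        vp_background=vp_background,
    )
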