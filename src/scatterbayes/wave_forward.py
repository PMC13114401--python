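"""Time-domain scalar wave propagation on a truncated half-space.

The physical model is the 2-D scalar wave equation

    rho(x) u_tt - div(mu(x) grad u) = f(t) g(x),

posed on the lower half-plane x2 <= 0 with a traction-free upper surface
(the transducer/geophone line Sigma) and zero initial data.  The source is
a Ricker pulse in time multiplied by a sum of narrow Gaussians centred at
the emitter positions.  For computation the half-space is truncated to a
rectangle R; the artificial side and bottom walls carry the first-order
non-reflecting condition  du/dn = -(1/c) u_t  with local wave speed
c = sqrt(mu/rho).

Discretisation: continuous piecewise-linear (P1) finite elements on a
structured triangulation with lumped mass, integrated in time by an
explicit leapfrog scheme; the boundary damping term is treated
semi-implicitly at the half step so the update stays explicit.  Receiver
traces are read off the discrete field by bilinear interpolation in space
and linear interpolation in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ConfigurationError",
    "StabilityError",
    "ResolutionWarning",
    "DomainSpec",
    "Scales",
    "Mesh",
    "MediumFields",
    "SourceSpec",
    "TimeGrid",
    "ObservationGrid",
    "TraceMatrix",
    "ricker_amplitude",
    "emitter_profile",
    "nondimensionalize",
    "dimensionalize",
    "assemble_system",
    "stable_dt",
    "solve_wave",
    "observe",
    "forward_traces",
    "energy_history",
    "WaveSolution",
]


class ConfigurationError(ValueError):
    """A geometric or physical configuration is inconsistent."""


class StabilityError(RuntimeError):
    """The requested time step violates the explicit stability bound."""


class ResolutionWarning(UserWarning):
    """The mesh underresolves the shortest wavelength of interest."""


# ----------------------------------------------------------------------
# domain, scales, mesh


@dataclass(frozen=True)
class DomainSpec:
    """Truncated rectangular computational domain R.

    Coordinates are non-dimensional.  ``y_range`` must lie at or below 0:
    the top edge (y = y_range[1]) is the physical surface Sigma where
    sources and receivers sit; the remaining three walls are artificial.
    """

    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.x_range[1] <= self.x_range[0] or self.y_range[1] <= self.y_range[0]:
            raise ConfigurationError("degenerate domain rectangle")
        if self.y_range[1] > 0.0:
            raise ConfigurationError("half-space truncation requires y <= 0")

    @property
    def width(self) -> float:
        return self.x_range[1] - self.x_range[0]

    @property
    def depth(self) -> float:
        return self.y_range[1] - self.y_range[0]

    @property
    def surface_y(self) -> float:
        return self.y_range[1]


@dataclass(frozen=True)
class Scales:
    """Characteristic scales (L, T, rho0) of the change of variables.

    x = L x', t = T t', rho = rho0 rho', mu = (rho0 L^2 / T^2) mu'.
    Derived scales follow: velocity L/T, frequency 1/T, and the source
    amplitude transforms as  f~ = (T^3 / (rho0 L)) f.
    """

    length: float = 1.0
    time: float = 1.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if min(self.length, self.time, self.density) <= 0.0:
            raise ConfigurationError("scales must be strictly positive")

    def factor(self, kind: str) -> float:
        """Dimensional value = factor * non-dimensional value."""
        L, T, r0 = self.length, self.time, self.density
        table = {
            "length": L,
            "time": T,
            "density": r0,
            "modulus": r0 * L**2 / T**2,
            "velocity": L / T,
            "frequency": 1.0 / T,
            "source_amplitude": r0 * L / T**3,
            "dimensionless": 1.0,
        }
        try:
            return table[kind]
        except KeyError:  # pragma: no cover - programming error
            raise ConfigurationError(f"unknown quantity kind {kind!r}") from None


def nondimensionalize(params: dict[str, tuple[float, str]], scales: Scales) -> dict[str, float]:
    """Scale a dict of ``name: (value, kind)`` dimensional parameters."""
    return {k: v / scales.factor(kind) for k, (v, kind) in params.items()}


def dimensionalize(params: dict[str, tuple[float, str]], scales: Scales) -> dict[str, float]:
    """Inverse of :func:`nondimensionalize`."""
    return {k: v * scales.factor(kind) for k, (v, kind) in params.items()}


@dataclass
class Mesh:
    """Structured triangulation of a rectangle.

    Nodes form an (nx+1) x (ny+1) grid; each cell is split into two
    triangles along its SW-NE diagonal.  Node ids are j*(nx+1)+i with i
    indexing x and j indexing y from the bottom upward, so the top row of
    nodes discretises Sigma.
    """

    domain: DomainSpec
    nx: int
    ny: int
    coords: np.ndarray = field(repr=False)  # (n_nodes, 2)
    triangles: np.ndarray = field(repr=False)  # (n_elements, 3)

    @classmethod
    def structured(cls, domain: DomainSpec, h: float) -> "Mesh":
        if h <= 0:
            raise ConfigurationError("mesh spacing must be positive")
        nx = max(1, round(domain.width / h))
        ny = max(1, round(domain.depth / h))
        return cls.regular(domain, nx, ny)

    @classmethod
    def regular(cls, domain: DomainSpec, nx: int, ny: int) -> "Mesh":
        x = np.linspace(*domain.x_range, nx + 1)
        y = np.linspace(*domain.y_range, ny + 1)
        X, Y = np.meshgrid(x, y)  # shape (ny+1, nx+1)
        coords = np.column_stack([X.ravel(), Y.ravel()])
        tris = []
        for j in range(ny):
            for i in range(nx):
                n00 = j * (nx + 1) + i
                n10 = n00 + 1
                n01 = n00 + (nx + 1)
                n11 = n01 + 1
                tris.append((n00, n10, n11))
                tris.append((n00, n11, n01))
        return cls(domain, nx, ny, coords, np.asarray(tris, dtype=np.int64))

    def refine(self, factor: int) -> "Mesh":
        """A nested mesh with ``factor`` times more cells per direction."""
        return Mesh.regular(self.domain, self.nx * factor, self.ny * factor)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def hx(self) -> float:
        return self.domain.width / self.nx

    @property
    def hy(self) -> float:
        return self.domain.depth / self.ny

    @property
    def h(self) -> float:
        return max(self.hx, self.hy)

    def element_centroids(self) -> np.ndarray:
        return self.coords[self.triangles].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        p = self.coords[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def top_nodes(self) -> np.ndarray:
        """Node ids on Sigma (the physical surface)."""
        return np.arange(self.ny * (self.nx + 1), (self.ny + 1) * (self.nx + 1))

    def artificial_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary edges on the non-reflecting walls.

        Returns (edges, elements): edges is (n_edges, 2) node-id pairs and
        elements the id of the triangle adjacent to each edge, used to take
        the local wave speed.
        """
        nx, ny = self.nx, self.ny
        edges = []
        elems = []

        def cell_tri(i: int, j: int, upper: bool) -> int:
            return 2 * (j * nx + i) + (1 if upper else 0)

        for i in range(nx):  # bottom wall, lower triangles
            edges.append((i, i + 1))
            elems.append(cell_tri(i, 0, upper=False))
        for j in range(ny):  # left wall, upper triangles of column 0
            edges.append((j * (nx + 1), (j + 1) * (nx + 1)))
            elems.append(cell_tri(0, j, upper=True))
        for j in range(ny):  # right wall, lower triangles of last column
            edges.append((j * (nx + 1) + nx, (j + 1) * (nx + 1) + nx))
            elems.append(cell_tri(nx - 1, j, upper=False))
        return np.asarray(edges, dtype=np.int64), np.asarray(elems, dtype=np.int64)


@dataclass
class MediumFields:
    """Piecewise-constant material coefficients on a mesh.

    ``rho`` and ``mu`` are per-element; the wave speed is c = sqrt(mu/rho).
    In the acoustic/geophysical reading mu = rho * vp**2.
    """

    rho: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.rho.shape != self.mu.shape:
            raise ConfigurationError("rho and mu must share a shape")
        if np.any(self.rho <= 0) or np.any(self.mu <= 0):
            raise ConfigurationError("material fields must be strictly positive")

    @classmethod
    def homogeneous(cls, mesh: Mesh, rho: float, mu: float) -> "MediumFields":
        n = mesh.n_elements
        return cls(np.full(n, float(rho)), np.full(n, float(mu)))

    @classmethod
    def from_velocity(cls, rho: np.ndarray, vp: np.ndarray) -> "MediumFields":
        rho = np.asarray(rho, dtype=float)
        vp = np.asarray(vp, dtype=float)
        return cls(rho, rho * vp**2)

    @property
    def c(self) -> np.ndarray:
        return np.sqrt(self.mu / self.rho)

    @property
    def vp(self) -> np.ndarray:
        return self.c


@dataclass(frozen=True)
class SourceSpec:
    """Simultaneous Ricker emission from K surface emitters.

    f(t) = f0 (1 - 2 pi^2 fM^2 t^2) exp(-pi^2 fM^2 t^2) in time and
    g(x) = (pi kappa)^(-n/2) sum_k exp(-|x - x_k|^2 / kappa) in space.
    """

    amplitude: float
    peak_frequency: float
    kappa: float
    centers: np.ndarray  # (K, 2)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, dtype=float)))
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.peak_frequency <= 0:
            raise ConfigurationError("peak frequency must be positive")
        if self.centers.shape[0] < 1:
            raise ConfigurationError("at least one emitter required")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform solver time grid starting at t=0 with zero initial data."""

    dt: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1:
            raise ConfigurationError("need dt > 0 and n_steps >= 1")

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps + 1)

    @property
    def duration(self) -> float:
        return self.dt * self.n_steps

    @classmethod
    def for_duration(cls, duration: float, dt: float) -> "TimeGrid":
        return cls(dt, int(np.ceil(duration / dt)))


@dataclass(frozen=True)
class ObservationGrid:
    """Receiver positions on Sigma and observation times t_m."""

    receivers: np.ndarray  # (J, 2)
    times: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "receivers", np.atleast_2d(np.asarray(self.receivers, float)))
        object.__setattr__(self, "times", np.asarray(self.times, float))
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("observation times must be strictly increasing")

    @property
    def n_receivers(self) -> int:
        return self.receivers.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def dimension(self) -> int:
        """Flattened data dimension D = J * M."""
        return self.n_receivers * self.n_times


@dataclass
class TraceMatrix:
    """J x M receiver recordings; flattening is receiver-major."""

    values: np.ndarray
    grid: ObservationGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (self.grid.n_receivers, self.grid.n_times)
        if self.values.shape != expect:
            raise ConfigurationError(f"trace shape {self.values.shape} != {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("traces contain non-finite values")

    def flatten(self) -> np.ndarray:
        return self.values.ravel()  # row-major = receiver-major


# ----------------------------------------------------------------------
# pointwise source formulas


def ricker_amplitude(t, f0: float, fM: float):
    """Ricker wavelet f(t) = f0 (1 - 2 pi^2 fM^2 t^2) exp(-pi^2 fM^2 t^2)."""
    t = np.asarray(t, dtype=float)
    a = (np.pi * fM) ** 2 * t**2
    out = f0 * (1.0 - 2.0 * a) * np.exp(-a)
    return out if out.ndim else float(out)


def emitter_profile(points, sources: SourceSpec):
    """Spatial emission profile g(x): a normalised sum of Gaussians."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = 2  # spatial dimension
    d2 = ((pts[:, None, :] - sources.centers[None, :, :]) ** 2).sum(axis=2)
    vals = np.exp(-d2 / sources.kappa).sum(axis=1) / (np.pi * sources.kappa) ** (n / 2)
    return vals if np.asarray(points).ndim > 1 else float(vals[0])


# ----------------------------------------------------------------------
# assembly


def assemble_system(mesh: Mesh, fields: MediumFields):
    """Discrete operators for the damped wave equation.

    Returns ``(mass, stiffness, damping)`` where mass and damping are the
    diagonals of lumped matrices (1-D arrays) and stiffness is CSR.  The
    damping diagonal is supported only on artificial-boundary nodes and
    carries the impedance rho*c = sqrt(mu*rho) of the adjacent element,
    which is the weak form of du/dn = -(1/c) u_t scaled by mu.
    """
    if fields.rho.shape[0] != mesh.n_elements:
        raise ConfigurationError("field arrays do not match the mesh element count")

    p = mesh.coords[mesh.triangles]  # (E, 3, 2)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * np.abs(det)

    # P1 shape-function gradients: b_i = rot(p_{i+1} - p_{i+2}) / (2A)
    bx = np.stack([p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]], 1)
    by = np.stack([p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]], 1)
    bx /= det[:, None]
    by /= det[:, None]

    ke = fields.mu[:, None, None] * area[:, None, None] * (
        bx[:, :, None] * bx[:, None, :] + by[:, :, None] * by[:, None, :]
    )
    rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
    cols = np.tile(mesh.triangles, (1, 3)).ravel()
    stiffness = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    mass = np.zeros(mesh.n_nodes)
    np.add.at(mass, mesh.triangles.ravel(), np.repeat(fields.rho * area / 3.0, 3))

    damping = np.zeros(mesh.n_nodes)
    edges, elems = mesh.artificial_edges()
    if edges.size:
        length = np.linalg.norm(mesh.coords[edges[:, 1]] - mesh.coords[edges[:, 0]], axis=1)
        imp = np.sqrt(fields.mu[elems] * fields.rho[elems])  # mu/c = sqrt(mu*rho)
        contrib = 0.5 * imp * length
        np.add.at(damping, edges[:, 0], contrib)
        np.add.at(damping, edges[:, 1], contrib)
    return mass, stiffness, damping


def node_areas(mesh: Mesh) -> np.ndarray:
    """Lumped quadrature weights (the unit-density lumped mass)."""
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.triangles.ravel(), np.repeat(mesh.element_areas() / 3.0, 3))
    return w


def _gershgorin_dt(mass: np.ndarray, stiffness: sp.csr_matrix) -> float:
    """Guaranteed-stable maximal leapfrog step from a Gershgorin bound.

    lambda_max(M^-1 K) <= max_i sum_j |K_ij| / M_i and the undamped
    leapfrog scheme is stable for dt <= 2/sqrt(lambda_max); the lumped
    boundary damping only removes energy and does not tighten the bound.
    """
    rowsum = np.abs(stiffness).sum(axis=1).A1 if hasattr(np.abs(stiffness).sum(axis=1), "A1") else np.asarray(np.abs(stiffness).sum(axis=1)).ravel()
    lam = float(np.max(rowsum / mass))
    return 2.0 / np.sqrt(lam)


def stable_dt(mesh: Mesh, fields: MediumFields, safety: float = 0.8) -> float:
    """A stable time step for the explicit scheme (CFL safety 0.8)."""
    mass, stiffness, _ = assemble_system(mesh, fields)
    return safety * _gershgorin_dt(mass, stiffness)


# ----------------------------------------------------------------------
# time stepping


@dataclass
class WaveSolution:
    """Discrete wavefield produced by :func:`solve_wave`.

    Either the full nodal history (n_steps+1, n_nodes) or only receiver
    series (J, n_steps+1) is stored, depending on the recording mode.
    """

    mesh: Mesh
    timegrid: TimeGrid
    history: np.ndarray | None = None
    receiver_series: np.ndarray | None = None
    receivers: np.ndarray | None = None


def _interp_matrix(mesh: Mesh, points: np.ndarray) -> sp.csr_matrix:
    """Bilinear interpolation weights from grid nodes to arbitrary points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x0, x1 = mesh.domain.x_range
    y0, y1 = mesh.domain.y_range
    eps = 1e-12 * max(mesh.domain.width, mesh.domain.depth)
    if np.any(pts[:, 0] < x0 - eps) or np.any(pts[:, 0] > x1 + eps) or np.any(
        pts[:, 1] < y0 - eps
    ) or np.any(pts[:, 1] > y1 + eps):
        raise ConfigurationError("interpolation point outside the domain")
    sx = np.clip((pts[:, 0] - x0) / mesh.hx, 0, mesh.nx - 1e-12)
    sy = np.clip((pts[:, 1] - y0) / mesh.hy, 0, mesh.ny - 1e-12)
    i = np.minimum(sx.astype(int), mesh.nx - 1)
    j = np.minimum(sy.astype(int), mesh.ny - 1)
    fx = sx - i
    fy = sy - j
    base = j * (mesh.nx + 1) + i
    rows = np.repeat(np.arange(pts.shape[0]), 4)
    cols = np.column_stack([base, base + 1, base + (mesh.nx + 1), base + (mesh.nx + 2)]).ravel()
    w = np.column_stack(
        [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
    ).ravel()
    return sp.csr_matrix((w, (rows, cols)), shape=(pts.shape[0], mesh.n_nodes))


def _check_resolution(mesh: Mesh, fields: MediumFields, sources: SourceSpec) -> None:
    lam_min = float(np.min(fields.c)) / sources.peak_frequency
    if lam_min / mesh.h < 2.0:
        warnings.warn(
            f"mesh spacing {mesh.h:.3g} underresolves the minimum wavelength "
            f"{lam_min:.3g} (< 2 elements per wavelength)",
            ResolutionWarning,
            stacklevel=3,
        )


def solve_wave(
    mesh: Mesh,
    fields: MediumFields,
    sources: SourceSpec,
    timegrid: TimeGrid,
    *,
    record: ObservationGrid | np.ndarray | None = None,
) -> WaveSolution:
    """Leapfrog integration of the damped semi-discrete wave equation.

    With lumped mass M, stiffness K, boundary damping C and load F(t):

        M (u+ - 2u + u-)/dt^2 + C (u+ - u-)/(2 dt) + K u = F(t_n)

    which is explicit because M and C are diagonal.  If ``record`` is
    given, only the interpolated values at those receiver positions are
    stored each step; otherwise the full nodal history is kept.
    """
    mass, stiffness, damping = assemble_system(mesh, fields)
    dt = timegrid.dt
    dt_max = _gershgorin_dt(mass, stiffness)
    if dt > dt_max:
        raise StabilityError(
            f"dt={dt:.4g} exceeds the stability bound {dt_max:.4g}; "
            "refine the time grid or coarsen the mesh"
        )
    _check_resolution(mesh, fields, sources)

    load = emitter_profile(mesh.coords, sources) * node_areas(mesh)
    a_plus = mass / dt**2 + damping / (2 * dt)
    a_mid = 2.0 * mass / dt**2
    a_minus = mass / dt**2 - damping / (2 * dt)

    n = mesh.n_nodes
    u_prev = np.zeros(n)
    u = np.zeros(n)

    rec_mat = None
    receivers = None
    if record is not None:
        receivers = record.receivers if isinstance(record, ObservationGrid) else np.atleast_2d(record)
        rec_mat = _interp_matrix(mesh, receivers)
        series = np.zeros((receivers.shape[0], timegrid.n_steps + 1))
        history = None
    else:
        history = np.zeros((timegrid.n_steps + 1, n))

    for step in range(timegrid.n_steps):
        t = step * dt
        f = ricker_amplitude(t, sources.amplitude, sources.peak_frequency)
        if step == 0:
            # Taylor start: with zero initial displacement and velocity the
            # first step is u^1 = dt^2/2 M^-1 F(0); a full-weight load here
            # would inject a spurious O(dt) initial velocity
            f *= 0.5
        u_next = (a_mid * u - stiffness @ u - a_minus * u_prev + f * load) / a_plus
        u_prev, u = u, u_next
        if rec_mat is not None:
            series[:, step + 1] = rec_mat @ u
        else:
            history[step + 1] = u

    if not np.all(np.isfinite(u)):  # pragma: no cover - guarded by CFL check
        raise StabilityError("wavefield blew up despite the CFL check")
    if rec_mat is not None:
        return WaveSolution(mesh, timegrid, receiver_series=series, receivers=receivers)
    return WaveSolution(mesh, timegrid, history=history)


def observe(solution: WaveSolution, obsgrid: ObservationGrid) -> TraceMatrix:
    """Sample a wavefield at receivers r_j and times t_m.

    Bilinear interpolation in space (if a full history was stored) and
    linear interpolation in time between solver steps.
    """
    times = solution.timegrid.times
    if obsgrid.times[0] < times[0] - 1e-12 or obsgrid.times[-1] > times[-1] + 1e-12:
        raise ConfigurationError("observation times outside the simulated window")

    if solution.receiver_series is not None:
        if solution.receivers is None or solution.receivers.shape != obsgrid.receivers.shape or not np.allclose(solution.receivers, obsgrid.receivers):
            raise ConfigurationError("recorded receivers do not match the observation grid")
        series = solution.receiver_series
    else:
        series = _interp_matrix(solution.mesh, obsgrid.receivers) @ solution.history.T

    # linear interpolation in time, vectorised over receivers
    dt = solution.timegrid.dt
    s = np.clip(obsgrid.times / dt, 0, len(times) - 1 - 1e-12)
    k = np.minimum(s.astype(int), len(times) - 2)
    frac = s - k
    vals = series[:, k] * (1 - frac) + series[:, k + 1] * frac
    return TraceMatrix(vals, obsgrid)


def forward_traces(
    mesh: Mesh,
    fields: MediumFields,
    sources: SourceSpec,
    obsgrid: ObservationGrid,
    *,
    dt: float | None = None,
    safety: float = 0.8,
) -> TraceMatrix:
    """One-call observation operator F: (rho, mu) -> receiver traces.

    Chooses an automatically stable time step unless ``dt`` is given,
    simulates up to the last observation time and samples the traces.
    This is the fast path used inside likelihood evaluations: only the
    receiver series is kept in memory.
    """
    if dt is None:
        mass, stiffness, _ = assemble_system(mesh, fields)
        dt = safety * _gershgorin_dt(mass, stiffness)
    timegrid = TimeGrid.for_duration(float(obsgrid.times[-1]), dt)
    sol = solve_wave(mesh, fields, sources, timegrid, record=obsgrid)
    return observe(sol, obsgrid)


def energy_history(solution: WaveSolution, fields: MediumFields) -> np.ndarray:
    """Discrete energy E_n = 1/2 v'Mv + 1/2 u'Ku along a stored history.

    The velocity is the centred difference (u_{n+1}-u_{n-1})/(2 dt), so
    the array has n_steps-1 entries (interior steps only).
    """
    if solution.history is None:
        raise ConfigurationError("energy requires a full stored history")
    mass, stiffness, _ = assemble_system(solution.mesh, fields)
    u = solution.history
    dt = solution.timegrid.dt
    v = (u[2:] - u[:-2]) / (2 * dt)
    kinetic = 0.5 * np.einsum("ij,j,ij->i", v, mass, v)
    potential = 0.5 * np.einsum("ij,ij->i", u[1:-1], (stiffness @ u[1:-1].T).T)
    return kinetic + potential
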