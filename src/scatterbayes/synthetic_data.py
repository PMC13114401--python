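"""Scenario fixtures and synthetic receiver data.

Three imaging setups are bundled as ready-made scenarios:

* ``scenario_tissue`` — shear-wave elastography of liver tissue: a
  homogeneous soft background (shear modulus 1.69 kPa, constant density)
  containing two stiff star-shaped scar-tissue anomalies (16 kPa), with
  49 surface transducers that first emit and then record;
* ``scenario_stratified`` — seismic imaging of a three-layer subsoil
  holding one tilted elliptic inclusion, with 51 sources and 52
  receivers on interspaced surface grids;
* ``scenario_salt_dome`` — a layered medium with a rising salt body
  whose cap screens two flank reservoir regions (oil and gas); the truth
  is expressed as corrector fields over the known background.

Data are generated by solving the forward model on a mesh finer than the
inversion mesh (default twice as fine) and adding i.i.d. Gaussian noise
d = d_true + eps with a noise level alpha in percent.  Two sigma recipes
are implemented: max-based, sigma_n = alpha max|d_true|/100, and
RMS-based, sigma_n = (alpha/100) sqrt(mean d_true^2).  Re-using the data
mesh for inversion is the classical inverse crime and triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from matplotlib.path import Path as PolyPath

from .bayes_core import (
    NoiseModel,
    PriorSpec,
    elliptic_constraint,
    elliptic_prior_cov,
    star_constraint,
    star_prior_cov,
)
from .geometry_params import (
    EllipticInclusion,
    InclusionSet,
    StarInclusion,
    pack_params,
    rasterize_fields,
    unpack_params,
)
from .wave_forward import (
    ConfigurationError,
    DomainSpec,
    MediumFields,
    Mesh,
    ObservationGrid,
    Scales,
    SourceSpec,
    TraceMatrix,
    forward_traces,
)

__all__ = [
    "Scenario",
    "InverseCrimeWarning",
    "scenario_tissue",
    "scenario_tissue_scaled",
    "scenario_stratified",
    "scenario_salt_dome",
    "generate_data",
    "noise_sigma",
    "split_halves",
    "make_forward",
    "tissue_prior",
    "stratified_prior",
    "layered_fields",
    "polygon_mask",
]


class InverseCrimeWarning(UserWarning):
    """Data and inversion share a discretisation."""


@dataclass
class Scenario:
    """A complete imaging configuration with a known ground truth."""

    name: str
    domain: DomainSpec
    scales: Scales
    sources: SourceSpec
    obsgrid: ObservationGrid
    mesh_h: float
    noise_alpha: float
    noise_recipe: str
    mode: str  # "tissue" | "elliptic" | "field"
    truth: InclusionSet | None = None
    n_inclusions: int = 1
    order: int = 0  # harmonic order Q for star modes
    background_fn: Callable[[Mesh], MediumFields] | None = None
    rho_background: float = 1.0
    mu_background: float | None = None
    vp_background: float | None = None
    truth_corrector: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None
    regions: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)
    material_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_recipe not in ("max", "rms"):
            raise ConfigurationError("noise recipe must be 'max' or 'rms'")
        surface = self.domain.surface_y
        if np.any(np.abs(self.obsgrid.receivers[:, 1] - surface) > 1e-12):
            raise ConfigurationError("receivers must sit on the surface Sigma")

    def build_mesh(self, refine: int = 1) -> Mesh:
        return Mesh.structured(self.domain, self.mesh_h / refine)

    def background_fields(self, mesh: Mesh) -> MediumFields:
        if self.background_fn is not None:
            return self.background_fn(mesh)
        if self.mode == "tissue":
            return MediumFields.homogeneous(mesh, self.rho_background, self.mu_background)
        return MediumFields.homogeneous(
            mesh, self.rho_background, self.rho_background * self.vp_background**2
        )

    def truth_fields(self, mesh: Mesh) -> MediumFields:
        """Rasterise the ground truth onto a mesh."""
        if self.mode == "field":
            bg = self.background_fields(mesh)
            drho, dvp = self.truth_corrector(mesh.element_centroids())
            return MediumFields.from_velocity(bg.rho + drho, bg.c + dvp)
        bg = None if self.background_fn is None else self.background_fields(mesh)
        return rasterize_fields(self.truth, mesh, background=bg)

    def true_params(self) -> np.ndarray:
        if self.truth is None:
            raise ConfigurationError("field scenarios have no inclusion parameter truth")
        return pack_params(self.truth)

    def kl_box(self) -> tuple[float, float]:
        """Side lengths of the corrector box (the full inversion rectangle)."""
        return self.domain.width, self.domain.depth

    def to_box(self, points: np.ndarray) -> np.ndarray:
        """Shift domain coordinates into the KL box [0,Lx] x [0,Ly]."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts - np.array([self.domain.x_range[0], self.domain.y_range[0]])


# ----------------------------------------------------------------------
# backgrounds and regions


def layered_fields(
    mesh: Mesh, interfaces: list[float], rhos: list[float], vps: list[float]
) -> MediumFields:
    """Horizontally layered medium: layer k sits above interfaces[k].

    ``interfaces`` are the (negative, decreasing) depths separating the
    len(interfaces)+1 layers listed top to bottom in ``rhos``/``vps``.
    """
    if len(rhos) != len(interfaces) + 1 or len(vps) != len(rhos):
        raise ConfigurationError("need one material per layer")
    y = mesh.element_centroids()[:, 1]
    idx = np.searchsorted(-np.asarray(interfaces), -y, side="left")
    rho = np.asarray(rhos, dtype=float)[idx]
    vp = np.asarray(vps, dtype=float)[idx]
    return MediumFields.from_velocity(rho, vp)


def polygon_mask(vertices: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Point-in-polygon indicator built on matplotlib's Path."""
    path = PolyPath(np.asarray(vertices, dtype=float))

    def mask(points: np.ndarray) -> np.ndarray:
        return path.contains_points(np.atleast_2d(np.asarray(points, dtype=float)))

    return mask


# ----------------------------------------------------------------------
# scenarios


def scenario_tissue() -> Scenario:
    """Liver-tissue elastography with two stiff star anomalies.

    Non-dimensionalised with L = 0.01 m, T = 0.01 s, rho0 = 1e3 kg/m^3:
    healthy shear modulus 1.69, scar anomalies 16, density 1 everywhere,
    Ricker peak frequency 0.5 (50 Hz), kappa = 2.  49 transducers on the
    surface from -12 to 12 in steps of 0.5 emit simultaneously and then
    record on the time grid [2, 11] with step 0.025 (recording starts
    only after the emission has died out).  Noise: 10% of the peak trace
    amplitude.  Truth geometry is a package fixture (the configuration is
    fully configurable); the anomalies are mildly non-circular stars.
    """
    scales = Scales(length=0.01, time=0.01, density=1e3)
    positions = np.arange(-12.0, 12.0 + 0.25, 0.5)
    transducers = np.column_stack([positions, np.zeros_like(positions)])
    Q = 5
    truth = InclusionSet(
        [
            StarInclusion(
                (-5.0, -7.0), 2.0,
                sin_coeffs=[0.0, 0.1, 0.0, 0.0, 0.0],
                cos_coeffs=[0.15, 0.0, 0.0, 0.0, 0.0],
                mu=16.0,
            ),
            StarInclusion(
                (5.0, -6.0), 1.6,
                sin_coeffs=[0.12, 0.0, 0.0, 0.0, 0.0],
                cos_coeffs=[0.0, -0.08, 0.0, 0.0, 0.0],
                mu=16.0,
            ),
        ],
        mode="tissue",
        rho_background=1.0,
        mu_background=1.69,
    )
    return Scenario(
        name="tissue",
        domain=DomainSpec((-15.0, 15.0), (-15.0, 0.0)),
        scales=scales,
        sources=SourceSpec(amplitude=1.0, peak_frequency=0.5, kappa=2.0, centers=transducers),
        obsgrid=ObservationGrid(transducers, np.arange(2.0, 11.0 + 1e-9, 0.025)),
        mesh_h=0.5,
        noise_alpha=10.0,
        noise_recipe="max",
        mode="tissue",
        truth=truth,
        n_inclusions=2,
        order=Q,
        rho_background=1.0,
        mu_background=1.69,
    )


def scenario_tissue_scaled() -> Scenario:
    """A desk-scale elastography configuration for end-to-end studies.

    Same physics and scales as :func:`scenario_tissue` but one circular
    anomaly (harmonic order Q = 2 in the inversion), 9 transducers on a
    smaller aperture, a shorter recording window and 5% noise — small
    enough that a full posterior sampling run takes minutes, not weeks.
    """
    positions = np.arange(-6.0, 6.0 + 0.75, 1.5)
    transducers = np.column_stack([positions, np.zeros_like(positions)])
    truth = InclusionSet(
        [StarInclusion((0.6, -3.4), 1.4, np.zeros(2), np.zeros(2), mu=16.0)],
        mode="tissue",
        rho_background=1.0,
        mu_background=1.69,
    )
    return Scenario(
        name="tissue-scaled",
        domain=DomainSpec((-7.5, 7.5), (-7.5, 0.0)),
        scales=Scales(length=0.01, time=0.01, density=1e3),
        sources=SourceSpec(amplitude=1.0, peak_frequency=0.5, kappa=2.0, centers=transducers),
        obsgrid=ObservationGrid(transducers, np.arange(2.0, 8.0 + 1e-9, 0.05)),
        mesh_h=0.5,
        noise_alpha=5.0,
        noise_recipe="max",
        mode="tissue",
        truth=truth,
        n_inclusions=1,
        order=2,
        rho_background=1.0,
        mu_background=1.69,
    )


_LAYER_INTERFACES = [-0.25, -0.55]
_LAYER_RHOS = [1.2, 1.8, 2.1]  # sandstone, limestone, shale
_LAYER_VPS = [2.0, 3.5, 4.4]


def scenario_stratified() -> Scenario:
    """Stratified subsoil with one tilted elliptic inclusion.

    Non-dimensionalised with L = 1 km, T = 1 s, rho0 = 1000 kg/m^3:
    three layers (sandstone, limestone, shale — densities up to 2.1 and
    velocities up to 4.4), Ricker peak frequency 2 (2 Hz), kappa = 0.04.
    K = 51 sources on [-1, 1] and J = 52 receivers on [-1.02, 1.02],
    interspaced with step 0.04; observation times 0 to 2.5 in steps of
    0.1; 10% RMS noise.  The layer depths and the inclusion geometry are
    package fixtures.
    """
    src_x = np.linspace(-1.0, 1.0, 51)
    rec_x = np.arange(-1.02, 1.02 + 1e-9, 0.04)
    sources = np.column_stack([src_x, np.zeros_like(src_x)])
    receivers = np.column_stack([rec_x, np.zeros_like(rec_x)])
    truth = InclusionSet(
        [EllipticInclusion((0.1, -0.4), (0.2, 0.1), 0.3, rho=1.5, vp=3.0)],
        mode="elliptic",
        rho_background=1.2,
        vp_background=2.0,
    )
    return Scenario(
        name="stratified",
        domain=DomainSpec((-1.3, 1.3), (-1.1, 0.0)),
        scales=Scales(length=1000.0, time=1.0, density=1e3),
        sources=SourceSpec(amplitude=100.0, peak_frequency=2.0, kappa=0.04, centers=sources),
        obsgrid=ObservationGrid(receivers, np.arange(0.0, 2.5 + 1e-9, 0.1)),
        mesh_h=0.05,
        noise_alpha=10.0,
        noise_recipe="rms",
        mode="elliptic",
        truth=truth,
        n_inclusions=1,
        background_fn=lambda mesh: layered_fields(
            mesh, _LAYER_INTERFACES, _LAYER_RHOS, _LAYER_VPS
        ),
        material_ranges={"rho": (1.2, 2.1), "vp": (2.0, 4.4)},
    )


_DOME_VERTICES = np.array(
    [(-0.35, -1.2), (0.35, -1.2), (0.15, -0.35), (-0.15, -0.35)]
)
_OIL_VERTICES = np.array(
    [(-0.75, -0.55), (-0.35, -0.55), (-0.40, -0.80), (-0.75, -0.80)]
)
_GAS_VERTICES = np.array(
    [(0.35, -0.50), (0.70, -0.50), (0.70, -0.75), (0.40, -0.75)]
)
_SALT_RHO, _SALT_VP = 1.1, 4.4
_OIL_RHO, _OIL_VP = 0.8, 1.3
_GAS_RHO, _GAS_VP = 0.3, 0.6


def scenario_salt_dome() -> Scenario:
    """Oil and gas reservoirs flanking a salt dome.

    The known background is the stratified medium plus the salt body (a
    buoyant low-density column whose cap screens what lies beneath).
    The ground truth adds two reservoir regions on the flanks — oil on
    the left, gas on the right — expressed as corrector fields over the
    background, which is the quantity the random-field parameterizations
    estimate.  Region masks for the dome, oil and gas areas are exposed
    for posterior field summaries.
    """
    src_x = np.linspace(-1.0, 1.0, 51)
    rec_x = np.arange(-1.02, 1.02 + 1e-9, 0.04)
    sources = np.column_stack([src_x, np.zeros_like(src_x)])
    receivers = np.column_stack([rec_x, np.zeros_like(rec_x)])

    dome = polygon_mask(_DOME_VERTICES)
    oil = polygon_mask(_OIL_VERTICES)
    gas = polygon_mask(_GAS_VERTICES)

    def background(mesh: Mesh) -> MediumFields:
        fields = layered_fields(mesh, _LAYER_INTERFACES, _LAYER_RHOS, _LAYER_VPS)
        mask = dome(mesh.element_centroids())
        rho = fields.rho.copy()
        vp = fields.c.copy()
        rho[mask] = _SALT_RHO
        vp[mask] = _SALT_VP
        return MediumFields.from_velocity(rho, vp)

    def corrector(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # background values at the points (layers are piecewise in depth)
        idx = np.searchsorted(-np.asarray(_LAYER_INTERFACES), -pts[:, 1], side="left")
        rho0 = np.asarray(_LAYER_RHOS)[idx]
        vp0 = np.asarray(_LAYER_VPS)[idx]
        drho = np.zeros(pts.shape[0])
        dvp = np.zeros(pts.shape[0])
        m_oil, m_gas = oil(pts), gas(pts)
        drho[m_oil] = _OIL_RHO - rho0[m_oil]
        dvp[m_oil] = _OIL_VP - vp0[m_oil]
        drho[m_gas] = _GAS_RHO - rho0[m_gas]
        dvp[m_gas] = _GAS_VP - vp0[m_gas]
        return drho, dvp

    return Scenario(
        name="salt-dome",
        domain=DomainSpec((-1.5, 1.5), (-1.2, 0.0)),
        scales=Scales(length=1000.0, time=1.0, density=1e3),
        sources=SourceSpec(amplitude=100.0, peak_frequency=2.0, kappa=0.04, centers=sources),
        obsgrid=ObservationGrid(receivers, np.arange(0.0, 2.5 + 1e-9, 0.1)),
        mesh_h=0.05,
        noise_alpha=10.0,
        noise_recipe="rms",
        mode="field",
        background_fn=background,
        truth_corrector=corrector,
        regions={"dome": dome, "oil": oil, "gas": gas},
        material_ranges={"rho": (0.3, 2.1), "vp": (0.6, 4.4)},
    )


# ----------------------------------------------------------------------
# data generation


def noise_sigma(d_true: np.ndarray, alpha: float, recipe: str) -> float:
    """Noise standard deviation from the percent level alpha.

    max recipe:  sigma_n = alpha max|d| / 100
    rms recipe:  sigma_n = (alpha/100) sqrt(sum |d|^2 / (J M))
    """
    if alpha < 0:
        raise ConfigurationError("noise level alpha must be non-negative")
    d = np.asarray(d_true, dtype=float)
    if recipe == "max":
        return alpha * float(np.max(np.abs(d))) / 100.0
    if recipe == "rms":
        return alpha / 100.0 * float(np.sqrt(np.mean(d**2)))
    raise ConfigurationError(f"unknown noise recipe {recipe!r}")


def generate_data(
    scenario: Scenario,
    fine_factor: int = 2,
    seed: int | None = None,
    alpha: float | None = None,
) -> tuple[np.ndarray, np.ndarray, NoiseModel | None]:
    """Synthetic data d = F(truth) + noise on a fine data mesh.

    The truth is solved on a mesh ``fine_factor`` times finer than the
    scenario's inversion mesh so that generation and inversion never
    share a discretisation; ``fine_factor=1`` commits the inverse crime
    and is flagged.  Returns the flattened noisy data, the noise-free
    data and the noise model (None when alpha = 0).
    """
    if fine_factor < 1:
        raise ConfigurationError("fine mesh factor must be >= 1")
    if fine_factor == 1:
        warnings.warn(
            "data mesh equals the inversion mesh: this is an inverse crime",
            InverseCrimeWarning,
            stacklevel=2,
        )
    if alpha is None:
        alpha = scenario.noise_alpha
    mesh = scenario.build_mesh(refine=fine_factor)
    fields = scenario.truth_fields(mesh)
    traces = forward_traces(mesh, fields, scenario.sources, scenario.obsgrid)
    d_true = traces.flatten()
    if alpha == 0.0:
        return d_true.copy(), d_true, None
    sigma = noise_sigma(traces.values, alpha, scenario.noise_recipe)
    rng = np.random.default_rng(seed)
    d = d_true + rng.normal(0.0, sigma, size=d_true.shape)
    noise = NoiseModel(sigma, d_true.size, alpha=alpha, recipe=scenario.noise_recipe)
    return d, d_true, noise


def split_halves(traces: TraceMatrix) -> tuple[TraceMatrix, TraceMatrix]:
    """Split recordings into two interspaced time grids of doubled step.

    One half feeds prior construction, the other the Bayesian inversion.
    With an odd number of observation times the final sample is dropped
    so the halves partition the remaining data.
    """
    vals, times = traces.values, traces.grid.times
    m = vals.shape[1]
    if m % 2 == 1:
        warnings.warn("odd number of observation times; dropping the final sample", stacklevel=2)
        vals, times = vals[:, :-1], times[:-1]
    g1 = ObservationGrid(traces.grid.receivers, times[0::2])
    g2 = ObservationGrid(traces.grid.receivers, times[1::2])
    return TraceMatrix(vals[:, 0::2], g1), TraceMatrix(vals[:, 1::2], g2)


# ----------------------------------------------------------------------
# forward operators and priors for the inclusion scenarios


def make_forward(
    scenario: Scenario, mesh: Mesh, safety: float = 0.8
) -> Callable[[np.ndarray], np.ndarray]:
    """Observation operator nu -> flattened traces on an inversion mesh."""
    if scenario.mode == "field":
        raise ConfigurationError("use a field forward built from a KL or Fourier basis")
    bg = None if scenario.background_fn is None else scenario.background_fields(mesh)

    def F(nu: np.ndarray) -> np.ndarray:
        incset = unpack_params(
            nu,
            scenario.mode,
            scenario.n_inclusions,
            scenario.order,
            rho_background=scenario.rho_background,
            mu_background=scenario.mu_background,
            vp_background=scenario.vp_background,
        )
        fields = rasterize_fields(incset, mesh, background=bg)
        return forward_traces(
            mesh, fields, scenario.sources, scenario.obsgrid, safety=safety
        ).flatten()

    return F


def tissue_prior(scenario: Scenario, s: float = 3.0, sigma_material: float = 20.0) -> PriorSpec:
    """Prior for star-tissue scenarios following the covariance recipe.

    The geometric prior mean mimics the output of a screening stage
    (approximate centres and sizes, no shape detail); the material prior
    mean is the healthy background modulus with a deliberately wide
    deviation, so the data alone decide the anomaly's nature.
    """
    Q, L = scenario.order, scenario.n_inclusions
    cov = star_prior_cov(Q, s=s, sigma_materials=(sigma_material,), n_inclusions=L)
    blocks = []
    for inc in scenario.truth.inclusions:
        block = np.zeros(2 * Q + 4)
        block[0:2] = np.round(inc.center * 2.0) / 2.0  # coarse location guess
        block[2] = round(inc.radius0 * 2.0) / 2.0  # coarse size guess
        block[-1] = scenario.mu_background
        blocks.append(block)
    mean = np.concatenate(blocks)
    return PriorSpec(mean, cov, constraint=star_constraint("tissue", L, Q))


def stratified_prior(scenario: Scenario) -> PriorSpec:
    """Prior for the elliptic scenario: geometry from migration-style
    information, materials blind at mid-range with half-range deviation."""
    L = scenario.n_inclusions
    cov, mean = elliptic_prior_cov(
        scenario.material_ranges["rho"], scenario.material_ranges["vp"], n_inclusions=L
    )
    for ell, inc in enumerate(scenario.truth.inclusions):
        mean[7 * ell : 7 * ell + 2] = np.round(inc.center * 5.0) / 5.0
        mean[7 * ell + 2 : 7 * ell + 4] = np.round(inc.semi_axes * 5.0) / 5.0
        mean[7 * ell + 4] = 0.0
    return PriorSpec(mean, cov, constraint=elliptic_constraint(L))
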