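# Methods

## Forward model

The scalar wave equation is non-dimensionalised by characteristic
length, time and density scales (L, T, rho0): x = L x', t = T t',
rho = rho0 rho', mu = (rho0 L^2/T^2) mu', which maps the source as
f~ = (T^3/(rho0 L)) f(T t). Tissue scenarios use L = 0.01 m, T = 0.01 s,
rho0 = 1e3 kg/m^3 (healthy shear modulus 1.69, scar 16, Ricker peak 0.5
i.e. 50 Hz); geophysical scenarios use L = 1 km, T = 1 s (velocities up
to 4.4, densities up to 2.1, Ricker peak 2 i.e. 2 Hz).

Space is discretised by continuous P1 triangles on a structured grid
(each cell split along its SW–NE diagonal) with **lumped mass**, time by
**explicit leapfrog** with the boundary-damping term centred at the half
step, so every update is a single sparse mat-vec. The artificial side
and bottom walls carry the first-order non-reflecting condition
du/dn = -(1/c) u_t, assembled edge-wise with the impedance
sqrt(mu rho) of the adjacent element; it is exact only for normal
incidence, so scenario geometry keeps inclusions interior and walls far
from steep incidence paths. Measured reflected energy for a normally
incident pulse is ~0.05% of incident (the guarantee asserted is <= 5%).

Two numerical choices deserve note:

* **Stability.** The leapfrog step is bounded through a Gershgorin
  estimate of lambda_max(M^-1 K), which is cheap, a guaranteed upper
  bound, and tight for this discretisation; solvers run at a 0.8 safety
  factor and raise an explicit error (never silent NaNs) when violated.
  Each likelihood evaluation picks its own stable step for the proposed
  medium; traces are compared on the fixed observation grid by linear
  interpolation in time (bilinear in space), so varying solver steps are
  harmless.
* **Startup.** With zero initial data the first leapfrog step takes the
  load at half weight (the Taylor start u^1 = dt^2/2 M^-1 F(0)); a
  full-weight first step injects a spurious O(dt) initial velocity and
  silently degrades the scheme to first order. With the half-weight
  start, receiver traces self-converge at observed order ~2 (asserted
  >= 1).

Meshes with fewer than 2 elements per minimum wavelength emit a
`ResolutionWarning` rather than an error: MCMC proposals occasionally
visit extreme material values, and rejecting them by likelihood is the
statistically correct response.

## Parameterizations and priors

**Star-shaped inclusions** use the normalised angle theta in [0, 1] and
radius a0 + 2 sum_q (c_q cos 2 pi q theta + s_q sin 2 pi q theta); per
inclusion the parameter block is (cx, cy, a0, s1, c1, ..., sQ, cQ) plus
one material (tissue: shear modulus; 2Q+4 entries) or two (density and
velocity; 2Q+5). Ellipses use (cx, cy, ax, ay, angle, rho, vp).
Rasterisation assigns each element the value of the inclusion containing
its centroid (last-listed wins on overlap — configurations of interest
are well separated, determinism is what matters), giving O(h) boundary
error that vanishes under refinement.

The tissue prior covariance is diagonal per block: 0.1 for centre
coordinates and leading radius, 0.1/(1+q^2)^3 for the order-q harmonic
pair (decay favours smooth, positive radii), and 20^2 for the shear
modulus — wide enough that the posterior alone decides between healthy,
scar and malignant stiffness. The elliptic prior is
diag(1, 1, 0.5, 0.5, 0.1, sigma_rho^2, sigma_vp^2) with material means
at mid-range of the layer values and sigma = half the range: a blind
materials prior. Admissibility M (radius positive on a 256-angle grid,
materials positive, additive fields positive at every element) is
enforced by zero prior mass — proposals outside M are rejected, never
projected, which preserves detailed balance.

**Corrector fields** write rho = rho0 + rho_c, vp = vp0 + vp_c over a
known background. The Fourier variant uses the classical double
expansion (constant term weighted 1/4, single-index terms 1/2) with
diagonal prior variances sigma0^2/(1+q^2+r^2)^s, s > 1 for summability.
The KL variant expands in the Dirichlet eigenfunctions
sqrt(4/(Lx Ly)) sin(pi q x/Lx) sin(pi r y/Ly) of the shifted Laplacian
on the corrector box (the full inversion rectangle), with covariance
eigenvalues lambda = mu^(-s), mu = tau^2 + pi^2 (q^2/Lx^2 + r^2/Ly^2).
Three conventions were genuinely open and are fixed as follows, each
with an escape hatch:

* the eigenvalue formula is implemented as the standard Dirichlet
  spectrum with squared box lengths (it reduces to the known -Laplacian
  spectrum at tau = 0);
* the mode index map is ell(q, r) = (q-1) Ny + r, the bijective choice
  for Nx != Ny; modes are then **sorted by descending eigenvalue** with
  (q, r)-lexicographic tie-breaks, which is what "dominant modes" means
  for truncation and for the FES split;
* the spectral exponent defaults to s = delta/2 with delta = gamma + n/2
  (gamma = 1/2, n = 2 gives s = 3/4); `MaternSpec(exponent="full")`
  selects s = delta for users who want covariance-operator decay.

The lognormal variant expands log rho - log rho0 instead, which makes
positivity unconditional; `lognormal_match` inverts the exact moment
identities sigma^2 = log(sigma0/mu0^2 + 1), mu = log mu0 - sigma^2/2.

## Samplers

AIES uses stretch moves with g(z) ~ 1/sqrt(z) on [1/a, a] (inverse
transform z = ((a-1)u+1)^2/a), a = 2 by default, acceptance
min(1, z^(N-1) ratio), and split-half parallel-style updates (half the
ensemble moves against the frozen other half, then they swap). The
W > 2N walker rule is enforced. Because stretch moves never leave the
affine span of the ensemble, a coordinate with zero spread across
walkers can never move; the samplers warn on such degenerate
initialisations, and the provided initialiser draws walkers from the
prior (rejection-resampled into M).

pCN proposes nu' = sqrt(1-beta^2) nu + beta xi with xi a centred prior
draw; acceptance depends only on the negative log-likelihood Phi, so the
rate does not collapse as the KL truncation grows (measured drift ~6
points from N = 8 to 128 at beta = 0.2; asserted <= 10). beta defaults
to 0.2 and is a pure tuning knob.

FES alternates, per sweep, AIES stretch moves on the E_L
largest-eigenvalue KL coordinates (conditional on the rest) with one pCN
sweep on the complement. E_L defaults to 8; tuning it is known to be
delicate. With E_L = 0 the sweep consumes the identical random stream as
the standalone pCN loop, so the two trajectories are bitwise equal at a
fixed seed — asserted in the tests. The two-field (density + velocity)
case is handled by concatenating the coefficient blocks into one state
vector; the walker rule W > 2 E_L applies to the moving block, with the
stricter published initialisation rule W > 4N + 1 available as a strict
mode. Burn-in defaults to the first 20% of stored steps; all samplers
are bitwise reproducible from a seed in serial mode.

## Synthetic data and scenarios

Data are always generated on a mesh finer than the inversion mesh
(default factor 2); sharing the discretisation is the inverse crime and
triggers a warning. Noise is i.i.d. Gaussian with sigma_n set by one of
two recipes from the level alpha (percent): max-based
sigma_n = alpha max|d|/100 (tissue, alpha = 10) or RMS-based
sigma_n = (alpha/100) RMS(d) (stratified, alpha = 10). Recordings can be
split into two interspaced half-rate grids (screening half / inversion
half).

The published truth geometries behind the reference figures are not
recoverable, so scenario truths are documented package fixtures: two
mildly non-circular stars (modulus 16) for tissue; one tilted ellipse
(rho 1.5, vp 3.0) in a three-layer sandstone/limestone/shale background
for the stratified case; and for the salt dome a buoyant salt column
(rho 1.1, vp 4.4) with a left-flank oil region (0.8, 1.3) and a
right-flank gas region (0.3, 0.6) expressed as corrector fields, with
region masks exposed for posterior field summaries. The generator
emulates simultaneous-source emission, fixed receiver/time grids, both
noise recipes and the mesh mismatch; it does not emulate sensor
directivity, attenuation, 3-D effects or non-Gaussian noise, so passing
tests certify the inference machinery, not field performance on real
recordings.

The desk-scale recovery study (`scenario_tissue_scaled`) keeps the
tissue physics but one circular anomaly (radius 1.4 at (0.6, -3.4)),
9 transducers, a [2, 8] recording window, alpha = 5, and an inversion
mesh of h = 0.5 — about 5 elements per background wavelength, the
coarsest resolution at which a likelihood-profile study showed the
modulus likelihood still peaks at the true stiffness rather than being
flattened by discretisation error. The screening-style prior rounds the
true centre and radius to a 0.5 grid (a deliberate mismatch of 0.14 in
centre and 0.1 in radius) and sets the material mean at the healthy
background with deviation 20. Under these conditions the posterior-mean
modulus lands within 30% of the truth and the MAP centre within a small
fraction of a radius, across noise seeds; the posterior shows the
expected radius–stiffness anticorrelation (a smaller, stiffer inclusion
scatters similarly), which is the dominant remaining uncertainty.

## Known limitations

2-D scalar physics only (no elastic vector waves, no PML, no
frequency-domain solver, no adjoint gradients); rectangular corrector
boxes; Matérn hyperparameters are configuration, not sampled; the
sampled-MAP is the best chain sample, not an optimised mode;
convergence diagnostics beyond acceptance rates and log-posterior
traces are out of scope.
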