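"""Validation studies: quantitative checks of solver and sampler quality.

Each function runs a self-contained numerical experiment at desk scale
and returns plain numbers, so the same studies back both the test suite
and the reproduction script.  The studies are:

* forward-solver self-convergence on a homogeneous tissue-scale medium;
* absorbing-boundary quality for a pulse normally incident on the
  bottom wall;
* AIES moment recovery on a badly scaled 2-D Gaussian;
* pCN prior invariance under a constant likelihood;
* FES pCN-block acceptance stability as the KL dimension grows;
* KL prior sampling against its analytic covariance;
* exactness of the closed-form pieces (Ricker, lognormal matching,
  noise recipes, prior covariance entries);
* end-to-end recovery of a stiff scar-tissue inclusion from noisy
  synthetic traces.
"""

from __future__ import annotations

import numpy as np

from .bayes_core import Posterior, star_prior_cov, elliptic_prior_cov
from .field_params import KLBasis, MaternSpec, kl_sample, lognormal_match
from .samplers import FESConfig, aies_run, fes_run, init_ensemble, pcn_run
from .summaries import map_estimate, mean_estimate
from .synthetic_data import (
    generate_data,
    make_forward,
    noise_sigma,
    scenario_tissue_scaled,
    tissue_prior,
)
from .wave_forward import (
    DomainSpec,
    MediumFields,
    Mesh,
    ObservationGrid,
    SourceSpec,
    forward_traces,
    ricker_amplitude,
)

__all__ = [
    "convergence_study",
    "absorbing_boundary_study",
    "aies_gaussian_study",
    "pcn_invariance_study",
    "fes_dimension_study",
    "kl_covariance_study",
    "closed_form_checks",
    "scar_recovery_study",
]


# ----------------------------------------------------------------------
# forward solver


def convergence_study(h_values=(0.4, 0.2, 0.1)) -> dict:
    """Trace self-convergence under nested mesh/time refinement.

    Homogeneous soft-tissue medium (rho = 1, mu = 1.69), one surface
    emitter, seven surface receivers.  Returns consecutive trace
    differences and the observed convergence order.
    """
    domain = DomainSpec((-5.0, 5.0), (-5.0, 0.0))
    source = SourceSpec(1.0, 0.5, 2.0, [(0.0, 0.0)])
    recs = np.column_stack([np.linspace(-3.0, 3.0, 7), np.zeros(7)])
    obs = ObservationGrid(recs, np.arange(1.0, 6.0 + 1e-9, 0.05))
    prev, errors = None, []
    for h in h_values:
        mesh = Mesh.structured(domain, h)
        fields = MediumFields.homogeneous(mesh, 1.0, 1.69)
        tr = forward_traces(mesh, fields, source, obs).values
        if prev is not None:
            errors.append(float(np.linalg.norm(tr - prev) / np.linalg.norm(tr)))
        prev = tr
    orders = [float(np.log2(errors[i] / errors[i + 1])) for i in range(len(errors) - 1)]
    return {"errors": errors, "order": min(orders), "orders": orders}


def absorbing_boundary_study(h: float = 0.2) -> dict:
    """Energy reflected by the artificial bottom wall, in percent.

    A surface pulse travels down a homogeneous medium (c = 1.3, depth 5)
    and hits the bottom wall at normal incidence; the co-located receiver
    trace is split into an incident window (before any echo can return,
    t < 5) and a reflection window around the bottom-echo arrival
    2 * depth / c = 7.7.  Side walls are far enough (|x| = 10) that their
    echoes land after the window.
    """
    domain = DomainSpec((-10.0, 10.0), (-5.0, 0.0))
    source = SourceSpec(1.0, 0.5, 2.0, [(0.0, 0.0)])
    obs = ObservationGrid([(0.0, 0.0)], np.arange(0.0, 12.0 + 1e-9, 0.02))
    mesh = Mesh.structured(domain, h)
    fields = MediumFields.homogeneous(mesh, 1.0, 1.69)
    trace = forward_traces(mesh, fields, source, obs).values[0]
    t = obs.times
    incident = trace[(t >= 0.0) & (t <= 5.0)]
    reflected = trace[(t >= 6.8) & (t <= 11.5)]
    percent = 100.0 * float(np.sum(reflected**2) / np.sum(incident**2))
    return {"reflected_energy_percent": percent}


# ----------------------------------------------------------------------
# samplers


def _autocorr_time(series: np.ndarray, max_lag: int = 400) -> float:
    x = series - series.mean()
    acf = np.correlate(x, x, mode="full")[x.size - 1 :]
    acf /= acf[0]
    tau = 1.0
    for k in range(1, min(max_lag, x.size)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return tau


def aies_gaussian_study(seed: int = 0, n_steps: int = 5000, n_walkers: int = 16) -> dict:
    """AIES on a 2-D centred Gaussian with variance ratio 1e4.

    Returns the recovered means in units of their standard error and the
    relative errors of the recovered variances.
    """
    var = np.array([1.0, 1.0e4])

    def lp(nu):
        nu = np.atleast_2d(nu)
        out = -0.5 * np.sum(nu**2 / var, axis=1)
        return out if out.size > 1 else float(out[0])

    rng = np.random.default_rng(seed)
    init = rng.normal(size=(n_walkers, 2)) * np.sqrt(var)
    chain = aies_run(lp, init, n_steps, a=2.0, rng=rng, seed=seed, vectorized=True)
    flat = chain.flat()
    mean_se_units, var_rel_err = [], []
    for k in range(2):
        tau = _autocorr_time(chain.samples[chain.burn_in_steps() :, :, k].mean(axis=1))
        n_eff = flat.shape[0] / tau
        se = np.sqrt(var[k] / n_eff)
        mean_se_units.append(float(abs(flat[:, k].mean()) / se))
        var_rel_err.append(float(abs(flat[:, k].var() / var[k] - 1.0)))
    return {
        "mean_se_units": max(mean_se_units),
        "var_rel_err": max(var_rel_err),
        "acceptance": chain.acceptance_rate,
    }


def pcn_invariance_study(
    seed: int = 0, n_modes_side: int = 8, n_steps: int = 3000, n_walkers: int = 16
) -> dict:
    """pCN under a constant likelihood must preserve the KL prior.

    All proposals are accepted (the acceptance ratio is identically 1)
    and the long-run marginal variance of every mode matches its
    covariance eigenvalue.  Uses N = n_modes_side^2 modes (64 by
    default) of a Matern-type prior.
    """
    grid = _unit_grid(16)
    basis = KLBasis.build(n_modes_side, n_modes_side, MaternSpec(tau=1.0), grid, 1.0, 1.0)
    std = np.sqrt(basis.eigenvalues)
    rng = np.random.default_rng(seed)
    init = rng.standard_normal((n_walkers, basis.n_modes)) * std
    chain = pcn_run(lambda nu: 0.0, std, init, n_steps, beta=0.9, rng=rng, seed=seed)
    emp = chain.flat().var(axis=0)
    return {
        "acceptance": chain.acceptance_rate,
        "var_max_rel_err": float(np.abs(emp / basis.eigenvalues - 1.0).max()),
        "n_modes": basis.n_modes,
    }


def fes_dimension_study(
    seed: int = 0, sides=((2, 4), (4, 8), (8, 16)), n_steps: int = 1500
) -> dict:
    """pCN-block acceptance as the KL dimension grows at fixed beta.

    The likelihood is a quadratic functional of the reconstructed field
    at one grid point, so it has a well-defined limit as more modes are
    added; a dimension-robust proposal keeps its acceptance rate in a
    narrow band as N grows 8 -> 128.
    """
    grid = _unit_grid(16)
    rates = {}
    for Nx, Ny in sides:
        basis = KLBasis.build(Nx, Ny, MaternSpec(tau=1.0), grid, 1.0, 1.0)
        w = basis.basis[:, grid.shape[0] // 2]

        def phi(nu, w=w):
            v = float(nu @ w)
            return 0.5 * v * v / 0.25

        std = np.sqrt(basis.eigenvalues)
        rng = np.random.default_rng(seed)
        init = rng.standard_normal((8, basis.n_modes)) * std
        config = FESConfig(n_low=2, beta=0.2)
        chain = fes_run(phi, std, config, init, n_steps, rng=rng, seed=seed)
        rates[basis.n_modes] = chain.meta["accept_high"]
    vals = list(rates.values())
    return {"acceptance_by_dim": rates, "drift_points": 100.0 * (max(vals) - min(vals))}


# ----------------------------------------------------------------------
# KL machinery


def _unit_grid(n: int) -> np.ndarray:
    x = (np.arange(n) + 0.5) / n
    X, Y = np.meshgrid(x, x)
    return np.column_stack([X.ravel(), Y.ravel()])


def kl_covariance_study(seed: int = 0, n_draws: int = 2000) -> dict:
    """Monte-Carlo covariance of KL field draws against P' Lambda P.

    2000 prior draws on a 16 x 16 grid with 16 retained modes; also
    checks discrete orthonormality of the sine eigenfunctions on a fine
    grid and monotonicity of the sorted eigenvalues.
    """
    spec = MaternSpec(tau=1.0)
    basis = KLBasis.build(4, 4, spec, _unit_grid(16), 1.0, 1.0)
    rng = np.random.default_rng(seed)
    draws = kl_sample(basis, rng, size=n_draws)
    fields = draws @ basis.basis
    emp = np.cov(fields.T, bias=True)
    target = basis.covariance()
    frob = float(np.linalg.norm(emp - target) / np.linalg.norm(target))

    fine = KLBasis.build(4, 4, spec, _unit_grid(64), 1.0, 1.0)
    gram = fine.basis @ fine.basis.T / fine.points.shape[0]
    gram_dev = float(np.abs(gram - np.eye(fine.n_modes)).max())
    monotone = bool(np.all(np.diff(basis.eigenvalues) <= 0))
    return {
        "cov_rel_frobenius": frob,
        "gram_max_dev": gram_dev,
        "eigenvalues_monotone": monotone,
    }


# ----------------------------------------------------------------------
# closed forms


def closed_form_checks() -> dict:
    """Absolute errors of the analytically known quantities.

    Ricker peak and zero crossing, lognormal moment matching, both noise
    sigma recipes against brute-force evaluation, and the printed prior
    covariance entries.
    """
    errs = {}
    errs["ricker_peak"] = abs(ricker_amplitude(0.0, 2.5, 50.0) - 2.5)
    t0 = 1.0 / (np.sqrt(2.0) * np.pi * 50.0)
    errs["ricker_zero_crossing"] = abs(ricker_amplitude(t0, 1.0, 50.0))

    mu, sigma2 = lognormal_match(1.0, np.e - 1.0)
    errs["lognormal_match"] = max(abs(mu + 0.5), abs(sigma2 - 1.0))
    mu, sigma2 = lognormal_match(3.7, 0.42)
    mean = np.exp(mu + sigma2 / 2.0)
    var = np.exp(2 * mu + sigma2) * (np.exp(sigma2) - 1.0)
    errs["lognormal_round_trip"] = max(abs(mean - 3.7), abs(var - 0.42))

    d = np.arange(12, dtype=float).reshape(3, 4) / 7.0 - 0.6
    brute_max = 9.0 * max(abs(v) for v in d.ravel()) / 100.0
    brute_rms = 9.0 / 100.0 * np.sqrt(sum(v**2 for v in d.ravel()) / d.size)
    errs["noise_sigma_max"] = abs(noise_sigma(d, 9.0, "max") - brute_max)
    errs["noise_sigma_rms"] = abs(noise_sigma(d, 9.0, "rms") - brute_rms)

    block = star_prior_cov(Q=5, s=3.0)
    errs["star_prior_harmonic"] = abs(block[3] - 0.1 / 8.0)
    errs["star_prior_material"] = abs(block[-1] - 400.0)
    var7, mean7 = elliptic_prior_cov((1.0, 2.1), (2.0, 4.4))
    errs["elliptic_prior_diag"] = float(
        np.abs(var7 - np.array([1, 1, 0.5, 0.5, 0.1, 0.55**2, 1.2**2])).max()
    )
    errs["elliptic_prior_mean"] = max(abs(mean7[5] - 1.55), abs(mean7[6] - 3.2))
    return {k: float(v) for k, v in errs.items()}


# ----------------------------------------------------------------------
# end-to-end recovery


def scar_recovery_study(
    seed: int = 1,
    n_seeds: int = 5,
    n_walkers: int = 40,
    n_steps: int = 400,
) -> dict:
    """Posterior recovery of one circular stiff inclusion in soft tissue.

    For each seed: synthetic data on a twice-finer mesh with 5% max-rule
    noise, AIES (a = 2) on the 8 posterior coordinates (centre, radius,
    two harmonic pairs, shear modulus) from a screening-style prior whose
    material mean is the healthy background.  A seed passes when the
    posterior-mean shear modulus is within 30% of the true 16 and the MAP
    contour centre within one true radius of the true centre.
    """
    scenario = scenario_tissue_scaled()
    mesh = scenario.build_mesh()
    prior = tissue_prior(scenario)
    nu_true = scenario.true_params()
    true_radius = scenario.truth.inclusions[0].radius0
    runs = []
    for k in range(n_seeds):
        sub = seed + 7919 * k  # distinct, reproducible per-seed streams
        d, _, noise = generate_data(scenario, seed=sub)
        posterior = Posterior(make_forward(scenario, mesh), d, noise, prior)
        rng = np.random.default_rng(sub + 1)
        init = init_ensemble(prior, n_walkers, rng=rng)
        chain = aies_run(posterior, init, n_steps, a=2.0, rng=rng, seed=sub)
        nu_map, _ = map_estimate(chain)
        mu_mean = float(mean_estimate(chain)[-1])
        center_err = float(np.hypot(*(nu_map[:2] - nu_true[:2])))
        all_in_m = bool(all(prior.constraint(nu) for nu in chain.flat(0)))
        finite = bool(np.all(np.isfinite(chain.log_posts)))
        runs.append(
            {
                "seed": sub,
                "posterior_mean_mu": mu_mean,
                "map_center_err": center_err,
                "acceptance": chain.acceptance_rate,
                "all_samples_in_M": all_in_m,
                "log_posts_finite": finite,
                "passes": (abs(mu_mean - 16.0) <= 0.3 * 16.0)
                and (center_err <= true_radius),
            }
        )
    return {
        "runs": runs,
        "n_pass": sum(r["passes"] for r in runs),
        "true_mu": 16.0,
        "true_radius": true_radius,
        "mean_mu_over_seeds": float(np.mean([r["posterior_mean_mu"] for r in runs])),
        "mean_center_err": float(np.mean([r["map_center_err"] for r in runs])),
    }
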