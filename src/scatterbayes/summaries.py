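"""Posterior postprocessing: MAP/mean estimates, probability maps,
parameter histograms and field summaries.

All summaries are pure functions of a chain record and a configuration,
so re-running them is bitwise stable.  For inclusion chains the central
product is the per-pixel probability that a point belongs to an anomaly;
for field chains it is the MAP and mean reconstructed fields together
with region-restricted value ranges and joint density-velocity
histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .field_params import BackgroundFields, KLBasis, kl_eval, total_fields
from .geometry_params import contains, unpack_params
from .samplers import ChainRecord
from .wave_forward import ConfigurationError

__all__ = [
    "map_estimate",
    "mean_estimate",
    "inclusion_probability_map",
    "parameter_histograms",
    "field_summaries",
    "FieldSummary",
]


def map_estimate(chain: ChainRecord) -> tuple[np.ndarray, float]:
    """The sampled MAP surrogate: the stored sample of highest log-posterior.

    Ties are broken by earliest occurrence; the result is invariant under
    any constant shift of the log-posterior.
    """
    if chain.samples.size == 0:
        raise ConfigurationError("empty chain")
    return chain.map_sample()


def mean_estimate(chain: ChainRecord, burn_in: int | float | None = None) -> np.ndarray:
    """Arithmetic mean over retained samples across all walkers."""
    flat = chain.flat(burn_in)
    if flat.shape[0] == 0:
        raise ConfigurationError("burn-in leaves no samples")
    return flat.mean(axis=0)


def inclusion_probability_map(
    chain: ChainRecord,
    points: np.ndarray,
    mode: str,
    n_inclusions: int,
    order: int = 0,
    burn_in: int | float | None = None,
    max_samples: int = 2000,
) -> np.ndarray:
    """Fraction of retained samples whose inclusion set contains each point.

    ``points`` is (n, 2); the result lies in [0, 1] pointwise.  At most
    ``max_samples`` evenly spaced retained samples are rasterised.
    """
    if mode == "field":
        raise ConfigurationError("probability maps are defined for inclusion chains")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    flat = chain.flat(burn_in)
    if flat.shape[0] > max_samples:
        sel = np.linspace(0, flat.shape[0] - 1, max_samples).astype(int)
        flat = flat[sel]
    counts = np.zeros(pts.shape[0])
    for nu in flat:
        incset = unpack_params(nu, mode, n_inclusions, order, mu_background=1.0, vp_background=1.0)
        inside = np.zeros(pts.shape[0], dtype=bool)
        for inc in incset.inclusions:
            inside |= contains(inc, pts)
        counts += inside
    return counts / flat.shape[0]


def parameter_histograms(
    chain: ChainRecord,
    which: list[int] | None = None,
    bins: int | str = "fd",
    burn_in: int | float | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """1-D histograms (counts, bin_edges) of selected coordinates.

    Bin choice defaults to Freedman-Diaconis ("fd"); pass an int for a
    fixed bin count.  Counts sum to the number of retained samples.
    """
    flat = chain.flat(burn_in)
    if flat.shape[0] == 0:
        raise ConfigurationError("no retained samples")
    if which is None:
        which = list(range(flat.shape[1]))
    out = {}
    for idx in which:
        vals = flat[:, idx]
        if isinstance(bins, str) and np.ptp(vals) == 0.0:
            edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
            out[idx] = (np.array([vals.size]), edges)
        else:
            out[idx] = np.histogram(vals, bins=bins)
    return out


@dataclass
class FieldSummary:
    """Reconstructed posterior fields with per-region value ranges.

    ``map_rho``/``map_vp`` come from the MAP coefficient vector;
    ``mean_rho``/``mean_vp`` from the mean coefficient vector (identical
    to the mean of per-sample fields in the additive mode by linearity,
    an approximation in the lognormal mode where the exact posterior-mean
    fields are reported separately); ``ranges`` maps region name to
    {"rho": (min, max), "vp": (min, max)} over the masked points.
    """

    map_rho: np.ndarray
    map_vp: np.ndarray
    mean_rho: np.ndarray
    mean_vp: np.ndarray
    exact_mean_rho: np.ndarray | None
    exact_mean_vp: np.ndarray | None
    ranges: dict = field(default_factory=dict)
    joint_histograms: dict = field(default_factory=dict)


def _fields_from_nu(
    nu: np.ndarray, basis: KLBasis, background: BackgroundFields, field_mode: str
):
    n = basis.n_modes
    rho_c = kl_eval(nu[:n], basis)
    vp_c = kl_eval(nu[n:], basis)
    return total_fields(background, rho_c, vp_c, mode=field_mode)


def field_summaries(
    chain: ChainRecord,
    basis: KLBasis,
    background: BackgroundFields,
    region_masks: dict[str, np.ndarray] | None = None,
    field_mode: str = "additive",
    burn_in: int | float | None = None,
    histogram_bins: int = 30,
    max_exact_samples: int = 500,
) -> FieldSummary:
    """Posterior field reconstruction for a KL (two-field) chain.

    The chain state concatenates the density and velocity coefficient
    blocks.  Region masks are boolean arrays over the basis grid points;
    for each region the (min, max) of the MAP and mean fields and a joint
    2-D (rho, vp) histogram of per-sample node values are produced.
    """
    if chain.dim != 2 * basis.n_modes:
        raise ConfigurationError("chain dimension does not match two KL blocks")
    nu_map, _ = map_estimate(chain)
    nu_mean = mean_estimate(chain, burn_in)
    f_map = _fields_from_nu(nu_map, basis, background, field_mode)
    f_mean = _fields_from_nu(nu_mean, basis, background, field_mode)

    # exact posterior-mean fields: average the per-sample fields (needed
    # in the lognormal mode where the map nu -> field is nonlinear)
    flat = chain.flat(burn_in)
    if flat.shape[0] > max_exact_samples:
        sel = np.linspace(0, flat.shape[0] - 1, max_exact_samples).astype(int)
        flat = flat[sel]
    n = basis.n_modes
    rho_acc = np.zeros(basis.points.shape[0])
    vp_acc = np.zeros(basis.points.shape[0])
    for nu in flat:
        f = _fields_from_nu(nu, basis, background, field_mode)
        rho_acc += f.rho
        vp_acc += f.vp
    exact_rho = rho_acc / flat.shape[0]
    exact_vp = vp_acc / flat.shape[0]

    summary = FieldSummary(
        f_map.rho, f_map.vp, f_mean.rho, f_mean.vp, exact_rho, exact_vp
    )
    if region_masks:
        for name, mask in region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape[0] != basis.points.shape[0]:
                raise ConfigurationError(f"mask {name!r} does not match the basis grid")
            summary.ranges[name] = {
                "map_rho": (float(f_map.rho[mask].min()), float(f_map.rho[mask].max())),
                "map_vp": (float(f_map.vp[mask].min()), float(f_map.vp[mask].max())),
                "mean_rho": (float(exact_rho[mask].min()), float(exact_rho[mask].max())),
                "mean_vp": (float(exact_vp[mask].min()), float(exact_vp[mask].max())),
            }
            # joint density-velocity histogram over samples and masked nodes
            rs, vs = [], []
            for nu in flat:
                f = _fields_from_nu(nu, basis, background, field_mode)
                rs.append(f.rho[mask])
                vs.append(f.vp[mask])
            H, re, ve = np.histogram2d(
                np.concatenate(rs), np.concatenate(vs), bins=histogram_bins
            )
            summary.joint_histograms[name] = (H, re, ve)
    return summary
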