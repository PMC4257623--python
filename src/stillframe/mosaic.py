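"""Effective mosaicity and mosaic block size from the (delta_psi, d) scatter.

Two physical effects let a reflection diffract slightly off the exact Bragg
condition.  Mutual rotation of mosaic blocks (plus beam divergence and
cell variation) spreads lattice points over arcs subtending a constant,
resolution-independent full angle ``eta`` at the reciprocal origin.  The
finite size ``D_eff`` of coherently diffracting domains expands each lattice
point into a sphere of reciprocal diameter ``alpha = 2 / D_eff``, which at
resolution ``d`` corresponds to an angular tolerance proportional to ``d``.
Together they define the acceptance envelope

    halfwidth(d) = eta / 2 + d / D_eff          (radians),

inside which |delta_psi| of an observed reflection must fall.

Two estimators are provided.  The binned least-squares fit groups the spots
25 per resolution bin, takes each bin's max |delta_psi| as an envelope
sample at the bin's mean d, and solves the straight-line normal equations.
The maximum-likelihood fit uses every spot: the per-spot likelihood is a
top-hat of half-width ``halfwidth(d_i)`` whose edges are smoothed by
logistic sigmoids of steepness ``epsilon`` (default 10) so the objective is
differentiable; the envelope that maximises the summed log-likelihood is
the narrowest one still covering the data, which systematically yields
smaller (more realistic) mosaicities than the bin-maximum fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MosaicEnvelope",
    "LikelihoodSettings",
    "InsufficientDataError",
    "envelope_halfwidth",
    "fit_envelope_ls",
    "fit_envelope_ml",
    "smoothed_tophat_logpdf",
    "plot_envelope",
]

_OPEN_DOMAIN_OFFSET = 1e-8


class InsufficientDataError(ValueError):
    """Too few records for the requested fit."""


@dataclass
class MosaicEnvelope:
    """Envelope parameters: full-width mosaicity (radians) and block size (angstroms).

    ``d_eff = math.inf`` encodes a vanishing size contribution (alpha = 0).
    Fit metadata (method, convergence flag, spot count) is attached by the
    fitting routines and is None for hand-built envelopes.
    """

    eta: float
    d_eff: float
    method: str | None = None
    converged: bool | None = None
    n_spots: int | None = None

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.d_eff <= 0:
            raise ValueError("d_eff must be positive (use math.inf for no size term)")

    @property
    def alpha(self) -> float:
        """Reciprocal-space spot diameter 2 / D_eff (1/angstrom)."""
        return 0.0 if math.isinf(self.d_eff) else 2.0 / self.d_eff

    @property
    def eta_deg_fullwidth(self) -> float:
        return math.degrees(self.eta)

    @property
    def eta_deg_halfwidth(self) -> float:
        """Half-width mosaicity eta/2 in degrees, the reporting convention."""
        return math.degrees(self.eta) / 2.0

    def halfwidth(self, d) -> np.ndarray | float:
        return envelope_halfwidth(self, d)


@dataclass(frozen=True)
class LikelihoodSettings:
    """Steepness of the logistic smoothing of the top-hat edges."""

    epsilon: float = 10.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def envelope_halfwidth(env: MosaicEnvelope, d):
    """Envelope half-width eta/2 + d/D_eff (radians) at resolution d (angstroms)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("resolution d must be positive")
    slope = 0.0 if math.isinf(env.d_eff) else 1.0 / env.d_eff
    out = env.eta / 2.0 + d * slope
    return float(out) if out.ndim == 0 else out


def _extract(records) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([r.d for r in records], dtype=float)
    dpsi = np.array([r.delta_psi for r in records], dtype=float)
    keep = np.isfinite(d) & np.isfinite(dpsi) & (d > 0)
    return d[keep], dpsi[keep]


def _envelope_from_line(intercept: float, slope: float, **meta) -> MosaicEnvelope:
    eta = max(0.0, 2.0 * intercept)
    d_eff = math.inf if slope <= 1e-300 else 1.0 / slope
    return MosaicEnvelope(eta=eta, d_eff=d_eff, **meta)


def bin_maxima(d: np.ndarray, dpsi: np.ndarray, bin_size: int = 25):
    """Sorted-by-d contiguous bins of ``bin_size`` spots; a final partial bin
    is merged into the previous one.  Returns (mean_d, max_abs_dpsi) per bin."""
    order = np.argsort(d)
    d, dpsi = d[order], np.abs(dpsi[order])
    n_bins = len(d) // bin_size
    edges = [i * bin_size for i in range(n_bins)] + [len(d)]
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        xs.append(d[lo:hi].mean())
        ys.append(dpsi[lo:hi].max())
    return np.array(xs), np.array(ys)


def fit_envelope_ls(records, bin_size: int = 25) -> MosaicEnvelope:
    """Binned least-squares envelope fit.

    Solves the straight-line normal equations for (eta/2, 1/D_eff) through
    the per-bin (mean d, max |delta_psi|) points; a negative estimate is
    clamped to zero and the remaining free parameter refitted.
    """
    d, dpsi = _extract(records)
    if len(d) < 2 * bin_size:
        raise InsufficientDataError(
            f"need at least {2 * bin_size} records for the binned fit, got {len(d)}"
        )
    meta = {"method": "ls", "converged": True, "n_spots": len(d)}
    if np.all(dpsi == 0.0):
        return MosaicEnvelope(eta=0.0, d_eff=math.inf, **meta)
    x, y = bin_maxima(d, dpsi, bin_size)
    n = len(x)
    sx, sxx, sy, sxy = x.sum(), (x * x).sum(), y.sum(), (x * y).sum()
    det = n * sxx - sx * sx
    intercept = (sy * sxx - sx * sxy) / det
    slope = (n * sxy - sx * sy) / det
    if intercept < 0.0:
        intercept = 0.0
        slope = sxy / sxx
    if slope < 0.0:
        slope = 0.0
        intercept = max(0.0, sy / n)
    return _envelope_from_line(intercept, slope, **meta)


def smoothed_tophat_logpdf(dpsi, halfwidth, epsilon: float = 10.0):
    """Log-density of the sigmoid-smoothed symmetric top-hat.

    The hard top-hat on [-w, w] has density 1/(2w).  Each edge is replaced
    by a logistic sigmoid whose argument is the offset normalised by the
    local half-width and scaled by ``epsilon``, so a single dimensionless
    steepness serves every resolution:

        log P = log sigma(eps (1 + t)) + log sigma(eps (1 - t)) - log(2 w),

    with t = delta_psi / w.  The normalisation uses the hard-top-hat width;
    the mass distortion from smoothing is below 1% at epsilon = 10.
    """
    t = np.asarray(dpsi, dtype=float) / halfwidth
    # log sigma(x) = -log(1 + exp(-x)), computed stably
    log_f = -np.logaddexp(0.0, -epsilon * (1.0 + t))
    log_g = -np.logaddexp(0.0, -epsilon * (1.0 - t))
    return log_f + log_g - np.log(2.0 * halfwidth)


def fit_envelope_ml(
    records,
    settings: LikelihoodSettings = LikelihoodSettings(),
    min_records: int = 10,
) -> MosaicEnvelope:
    """Smoothed top-hat maximum-likelihood envelope fit over all spots.

    The summed log-likelihood diverges to -inf when the envelope shrinks
    below the data and decays as it grows without bound, so an interior
    maximum exists.  Positivity of (eta/2, 1/D_eff) is enforced by
    optimising their logarithms (offset by 1e-8 to keep the domain open)
    with a quasi-Newton method, initialised from the least-squares fit.  On
    optimizer failure the least-squares envelope is returned flagged as not
    converged.
    """
    d, dpsi = _extract(records)
    if len(d) < min_records:
        raise InsufficientDataError(f"need at least {min_records} records, got {len(d)}")
    try:
        init = fit_envelope_ls(records)
        c0 = init.eta / 2.0
        c1 = 0.0 if math.isinf(init.d_eff) else 1.0 / init.d_eff
    except InsufficientDataError:
        c0 = 0.25 * float(np.max(np.abs(dpsi))) if np.any(dpsi) else 0.0
        c1 = float(np.median(np.abs(dpsi) / d))
    # ensure a covering, strictly positive starting envelope
    max_ratio = float(np.max(np.abs(dpsi) / d)) if len(d) else 0.0
    c0 = max(c0, _OPEN_DOMAIN_OFFSET)
    c1 = max(c1, 0.5 * max_ratio, _OPEN_DOMAIN_OFFSET)
    eps = settings.epsilon

    def nll(u: np.ndarray) -> float:
        w = (np.exp(u[0]) - _OPEN_DOMAIN_OFFSET).clip(0.0) \
            + (np.exp(u[1]) - _OPEN_DOMAIN_OFFSET).clip(0.0) * d
        w = np.maximum(w, 1e-12)
        return -float(np.sum(smoothed_tophat_logpdf(dpsi, w, eps)))

    u0 = np.log([c0 + _OPEN_DOMAIN_OFFSET, c1 + _OPEN_DOMAIN_OFFSET])
    opt = minimize(nll, u0, method="L-BFGS-B",
                   bounds=[(math.log(1e-10), math.log(1.0))] * 2,
                   options={"maxiter": 200})
    meta = {"method": "ml", "n_spots": len(d)}
    if not np.all(np.isfinite(opt.x)):
        ls = fit_envelope_ls(records)
        return MosaicEnvelope(eta=ls.eta, d_eff=ls.d_eff, converged=False, **meta)
    half_eta = max(0.0, math.exp(opt.x[0]) - _OPEN_DOMAIN_OFFSET)
    slope = max(0.0, math.exp(opt.x[1]) - _OPEN_DOMAIN_OFFSET)
    return _envelope_from_line(half_eta, slope, converged=bool(opt.success), **meta)


def plot_envelope(records, env: MosaicEnvelope, wavelength: float, ax=None):
    """Scatter delta-psi against the diffraction angle 2-theta with the fitted
    envelope and its size-only inner component overlaid."""
    import matplotlib.pyplot as plt

    d, dpsi = _extract(records)
    if ax is None:
        _, ax = plt.subplots()
    two_theta = np.degrees(2.0 * np.arcsin(np.clip(wavelength / (2.0 * d), -1, 1)))
    ax.plot(two_theta, np.degrees(dpsi), "o", ms=3, alpha=0.6, label="bright spots")
    dd = np.linspace(d.min(), d.max(), 200)
    tt = np.degrees(2.0 * np.arcsin(np.clip(wavelength / (2.0 * dd), -1, 1)))
    w = np.degrees(envelope_halfwidth(env, dd))
    ax.plot(tt, w, "g-", label=r"$\pm(\eta/2 + d/D_\mathrm{eff})$")
    ax.plot(tt, -w, "g-")
    if not math.isinf(env.d_eff):
        ws = np.degrees(dd / env.d_eff)
        ax.plot(tt, ws, "r--", lw=0.8, label=r"$\pm d/D_\mathrm{eff}$")
        ax.plot(tt, -ws, "r--", lw=0.8)
    ax.set_xlabel(r"$2\theta$ (degrees)")
    ax.set_ylabel(r"$\Delta\psi$ (degrees)")
    ax.legend(fontsize=8)
    return ax
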