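"""Calibration oracle for within-person watch-time spread.

The association models use the daily absolute deviation of a watch-time
variable from the participant's own long-run mean as the outcome.  The
simulator, however, is parameterised by within-person *standard deviations*
of wake and bed times.  This module provides the bridge: a semi-analytic
expression for the population mean absolute deviation (MAD) of a
truncated-normal watch time, and a root solver that inverts it so that a
target MAD (and hence a target group contrast in the fitted models) maps
back to a within-person SD.

The model: a participant has a latent daily mean ``mu ~ N(mu_pop, sd_between)``.
On an analysable day the observed time is normal around ``mu`` with
within-person SD ``sigma``, restricted to the analysis window ``[a, b]``
(days falling outside the window are excluded upstream, so the law of the
retained days is the doubly truncated normal).  The participant-level MAD is
``E|X - m(mu)|`` with ``m(mu)`` the truncated-normal mean; the population MAD
averages this over the latent means with Gauss-Hermite quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, special

__all__ = [
    "truncnorm_mean",
    "truncnorm_abs_dev",
    "population_mad",
    "solve_within_sd",
    "calibrate_within_sds",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _phi(z):
    return np.exp(-0.5 * z * z) / _SQRT_2PI


def _Phi(z):
    return 0.5 * (1.0 + special.erf(z / _SQRT2))


def _partial_mean(mu, sigma, lo, hi):
    """Integral of x*phi((x-mu)/sigma)/sigma over [lo, hi] (untruncated mass)."""
    zl = (lo - mu) / sigma
    zh = (hi - mu) / sigma
    return mu * (_Phi(zh) - _Phi(zl)) - sigma * (_phi(zh) - _phi(zl))


def truncnorm_mean(mu, sigma, a, b):
    """Mean of N(mu, sigma^2) truncated to [a, b]."""
    za = (a - mu) / sigma
    zb = (b - mu) / sigma
    z = _Phi(zb) - _Phi(za)
    return mu + sigma * (_phi(za) - _phi(zb)) / z


def truncnorm_abs_dev(mu, sigma, a, b, center=None):
    """E|X - c| for X ~ N(mu, sigma^2) truncated to [a, b].

    ``center`` defaults to the truncated mean, giving the participant-level
    mean absolute deviation.  Closed form via partial expectations.
    """
    za = (a - mu) / sigma
    zb = (b - mu) / sigma
    z = _Phi(zb) - _Phi(za)
    c = truncnorm_mean(mu, sigma, a, b) if center is None else center
    zc = (c - mu) / sigma
    mass_lo = _Phi(zc) - _Phi(za)
    mass_hi = _Phi(zb) - _Phi(zc)
    lower = c * mass_lo - _partial_mean(mu, sigma, a, c)
    upper = _partial_mean(mu, sigma, c, b) - c * mass_hi
    return (lower + upper) / z


def _population_mad_fixed_sigma(sigma, window, mu_pop, sd_between, n_quad):
    a, b = window
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    mus = mu_pop + sd_between * nodes
    za = (a - mus) / sigma
    zb = (b - mus) / sigma
    mass = _Phi(zb) - _Phi(za)
    ok = mass > 1e-12  # extreme nodes carry negligible weight; avoid 0/0
    vals = np.zeros_like(mus)
    vals[ok] = truncnorm_abs_dev(mus[ok], sigma, a, b)
    # probabilists' Hermite weights sum to sqrt(2*pi)
    return float(np.sum(weights * vals) / _SQRT_2PI)


def population_mad(sigma, window, mu_pop, sd_between, het_sigma=0.0, n_quad=80):
    """Population mean absolute deviation of a watch-time variable.

    Averages the participant-level MAD over latent means
    ``mu ~ N(mu_pop, sd_between)`` and, when ``het_sigma > 0``, over a
    mean-one lognormal person-level multiplier on the within-person SD
    (trait heterogeneity in routine variability), both via Gauss-Hermite
    quadrature.
    """
    if het_sigma <= 0:
        return _population_mad_fixed_sigma(sigma, window, mu_pop, sd_between, n_quad)
    nodes, weights = np.polynomial.hermite_e.hermegauss(32)
    mults = np.exp(-0.5 * het_sigma**2 + het_sigma * nodes)  # E[mult] = 1
    vals = np.array(
        [
            _population_mad_fixed_sigma(sigma * m, window, mu_pop, sd_between, n_quad)
            for m in mults
        ]
    )
    return float(np.sum(weights * vals) / _SQRT_2PI)


def _mad_plateau(window):
    # sigma -> inf: truncated normal tends to uniform on the window,
    # whose mean absolute deviation is width/4.
    return (window[1] - window[0]) / 4.0


def solve_within_sd(target_mad, window, mu_pop, sd_between, het_sigma=0.0, n_quad=80):
    """Invert ``population_mad`` for sigma by bracketed root finding.

    Raises ValueError when the target exceeds the supremum attainable on the
    window (the uniform-limit MAD of width/4).
    """
    plateau = _mad_plateau(window)
    if not 0 < target_mad < plateau:
        raise ValueError(
            f"target MAD {target_mad:.1f} min not attainable on window "
            f"{window} (supremum {plateau:.1f} min)"
        )

    def f(sigma):
        return population_mad(sigma, window, mu_pop, sd_between, het_sigma, n_quad) - target_mad

    lo, hi = 1e-3, 10.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e5:
            raise RuntimeError("failed to bracket sigma")
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def calibrate_within_sds(
    mad_targets,
    window,
    mu_pop,
    sd_between,
    het_sigma=0.0,
):
    """Within-person SDs reproducing per-group MAD targets (minutes).

    ``mad_targets`` is a (referent, prediabetes, diabetes) triple of target
    population MADs; the return value is the matching triple of within-person
    SDs under the configured latent-mean distribution and person-level
    variability heterogeneity.
    """
    return tuple(
        solve_within_sd(t, window, mu_pop, sd_between, het_sigma) for t in mad_targets
    )
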