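"""Exponential tilting: the missing-value distribution implied by a DPC.

Under a logit-linear detection model, Bayes' theorem links the density of
the values that went missing to the density of the values that were
observed by an exponential tilt:

    f_mis(y) = exp(-b1 * y) * f_obs(y) / M_obs(-b1),

where ``M_obs`` is the moment generating function of the observed
distribution.  When the observed intensities are Normal(mu_obs, sigma2),
the tilted density is again normal with the same variance and mean
``mu_obs - b1 * sigma2``: missingness shifts the distribution down by
``b1 * sigma_obs`` standard deviations without reshaping it.

The same machinery yields the marginal (unconditional-on-y) detection
probability and the Fisher information that the missing-value count
carries about a feature's mean, relative to the information in the
observed intensities themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as logit_fn


__all__ = [
    "TiltedNormal",
    "InfoSummary",
    "tilt_normal",
    "tilt_density",
    "marginal_detection_prob",
    "fisher_info",
]


@dataclass(frozen=True)
class TiltedNormal:
    """Observed/missing normal pair linked by exponential tilting."""

    mu_obs: float
    sigma2: float
    beta1: float
    mu_mis: float
    shift: float  # beta1 * sigma_obs, in SD units; scale-invariant

    def pdf_obs(self, y: np.ndarray) -> np.ndarray:
        return _normal_pdf(y, self.mu_obs, self.sigma2)

    def pdf_mis(self, y: np.ndarray) -> np.ndarray:
        return _normal_pdf(y, self.mu_mis, self.sigma2)


@dataclass(frozen=True)
class InfoSummary:
    """Fisher information about mu_obs from intensities (I1) vs missingness (I2)."""

    n: int
    p: float
    sigma2: float
    beta1: float
    I1: float
    I2: float
    ratio: float
    mu_from_p: float | None = None


def _normal_pdf(y, mu, sigma2):
    y = np.asarray(y, dtype=float)
    if sigma2 == 0:
        out = np.where(y == mu, np.inf, 0.0)
        return out
    return np.exp(-((y - mu) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)


def tilt_normal(mu_obs: float, sigma2: float, beta1: float) -> TiltedNormal:
    """Closed-form tilt of a normal observed-value distribution.

    The missing-value distribution is Normal(mu_obs - beta1*sigma2, sigma2).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return TiltedNormal(
        mu_obs=float(mu_obs),
        sigma2=float(sigma2),
        beta1=float(beta1),
        mu_mis=float(mu_obs - beta1 * sigma2),
        shift=float(beta1 * np.sqrt(sigma2)),
    )


def tilt_density(grid: np.ndarray, f_obs: np.ndarray, beta1: float,
                 tail_tol: float = 1e-8) -> np.ndarray:
    """Numerically tilt a tabulated observed density to the missing one.

    ``f_obs`` is evaluated on a (sorted, effectively uniform) ``grid`` that
    must carry essentially all of the tilted mass; the tilt multiplies by
    ``exp(-beta1*y)`` and renormalises by the trapezoid estimate of
    ``M_obs(-beta1)``.  Raises if the grid looks too narrow, i.e. the
    boundary values of the tilted density are non-negligible relative to
    its peak.
    """
    grid = np.asarray(grid, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    if grid.shape != f_obs.shape or grid.ndim != 1:
        raise ValueError("grid and f_obs must be 1-D arrays of equal length")
    if np.any(f_obs < 0):
        raise ValueError("f_obs must be non-negative")
    # work relative to the grid centre so exp(-b1*y) cannot overflow
    y0 = 0.5 * (grid[0] + grid[-1])
    w = np.exp(-beta1 * (grid - y0)) * f_obs
    M = np.trapezoid(w, grid)
    if M <= 0:
        raise ValueError("tilted mass is zero on the grid")
    f_mis = w / M
    dy = np.median(np.diff(grid))
    edge_mass = (f_mis[0] + f_mis[-1]) * dy
    if edge_mass > tail_tol:
        raise ValueError(
            f"grid too narrow for stable tilting: boundary mass ~{edge_mass:.2e} "
            f"exceeds {tail_tol:.0e}"
        )
    return f_mis


def marginal_detection_prob(mu_obs: float, sigma2: float, beta0: float,
                            beta1: float) -> float:
    """Marginal detection probability, averaging the DPC over intensity.

    logit p(d=1) = beta0 + beta1*mu_obs - (1/2)*beta1^2*sigma2, which is
    also beta0 + beta1*(mu_mis + mu_obs)/2.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return float(expit(beta0 + beta1 * mu_obs - 0.5 * beta1**2 * sigma2))


def fisher_info(n: int, p: float, sigma2: float, beta1: float,
                beta0: float | None = None) -> InfoSummary:
    """Fisher information about a feature mean from two sources.

    I1 = n*p/sigma2 comes from the (on average n*p) observed intensities;
    I2 = n*beta1^2*p*(1-p) comes from the binomial missing-value count,
    whose success probability is logit-linear in the mean with slope beta1.
    Their ratio I2/I1 = beta1^2*(1-p)*sigma2 measures how much of the
    information recoverable from missingness is relative to what the
    observed values already carry.

    When ``beta0`` is given, also inverts the marginal DPC to recover the
    mean implied by a detection proportion ``p``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive for I1")
    I1 = n * p / sigma2
    I2 = 0.0 if p in (0.0, 1.0) else n * beta1**2 * p * (1 - p)
    ratio = beta1**2 * (1 - p) * sigma2
    mu_from_p = None
    if beta0 is not None:
        if beta1 == 0:
            raise ValueError("mean not identifiable from missingness when beta1=0")
        mu_from_p = float((logit_fn(p) - beta0 + beta1**2 * sigma2 / 2.0) / beta1)
    return InfoSummary(n=int(n), p=float(p), sigma2=float(sigma2),
                       beta1=float(beta1), I1=float(I1), I2=float(I2),
                       ratio=float(ratio), mu_from_p=mu_from_p)
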