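"""Zero-truncated binomial distribution.

The number of samples in which a feature is detected, conditional on the
feature being detected at least once, follows a binomial distribution
truncated at zero:

    P(D = k | D >= 1) = C(n, k) p^k (1-p)^(n-k) / (1 - (1-p)^n),  k = 1..n.

Features missing in every sample never enter the dataset, so fitting the
plain binomial to the observed detection counts overstates detection
probabilities at low intensity; the truncated form is the correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


__all__ = ["ztbinom_logpmf", "ztbinom_pmf", "log1m_pow"]


def log1m_pow(n, log_q: np.ndarray) -> np.ndarray:
    """log(1 - q^n) computed from log(q), stable for q near 0 and 1."""
    x = n * np.asarray(log_q, dtype=float)  # log(q^n), <= 0
    # log(1 - e^x): use log1p(-e^x) when e^x is small, log(-expm1(x)) otherwise
    with np.errstate(divide="ignore"):
        out = np.where(
            x < -0.6931471805599453,
            np.log1p(-np.exp(x)),
            np.log(-np.expm1(np.where(x < 0, x, -np.inf))),
        )
    return out


def ztbinom_logpmf(k, n, p) -> np.ndarray:
    """Log-pmf of the zero-truncated binomial, vectorised.

    Valid for ``1 <= k <= n`` and ``0 < p <= 1``; stable down to p ~ 1e-12
    (the binomial term and the truncation mass are both evaluated in log
    space via log1p).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any((k < 1) | (k > n)):
        raise ValueError("k must satisfy 1 <= k <= n")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p must be in (0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 gives log q = -inf, handled below
        log_q = np.log1p(-p)
    base = stats.binom.logpmf(k, n, p)
    denom = log1m_pow(n, log_q)
    # p == 1: truncation mass is 1, denom underflows to log(0) -> fix to 0
    denom = np.where(p == 1.0, 0.0, denom)
    return base - denom


def ztbinom_pmf(k, n, p):
    """Pmf of the zero-truncated binomial; see :func:`ztbinom_logpmf`."""
    return np.exp(ztbinom_logpmf(k, n, p))
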