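"""Intensity matrix container and per-feature summaries.

The central data structure is a feature-by-sample matrix of log2
intensities together with a detection mask: ``mask[i, j] == 1`` means the
intensity of feature *i* was reported (detected) in sample *j*, while
``mask[i, j] == 0`` means it is missing and ``values[i, j]`` carries no
usable number.  Per-feature summaries (detected counts, observed means,
sample variances and their empirical-Bayes moderated versions) feed the
detection-probability-curve fits and the differential-expression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special


__all__ = [
    "IntensityMatrix",
    "FeatureSummary",
    "summarize_features",
    "squeeze_variances",
]


@dataclass
class IntensityMatrix:
    """Feature x sample log2-intensity matrix with an explicit detection mask.

    Parameters
    ----------
    values
        2-D float array of log2 intensities. Entries where ``mask`` is 0 are
        ignored (they may be NaN).
    mask
        2-D {0,1} array of the same shape; 1 marks a detected value.
    feature_ids, sample_ids
        Optional identifiers; generated if omitted.
    """

    values: np.ndarray
    mask: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("matrix must have at least 1 feature and 1 sample")
        self.mask = (self.mask != 0).astype(np.int8)
        if not np.all(np.isfinite(self.values[self.mask == 1])):
            raise ValueError("detected entries must be finite")
        if not self.feature_ids:
            self.feature_ids = [f"feature_{i + 1}" for i in range(self.n_features)]
        if not self.sample_ids:
            self.sample_ids = [f"sample_{j + 1}" for j in range(self.n_samples)]
        if len(self.feature_ids) != self.n_features:
            raise ValueError("feature_ids length mismatch")
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def masked(self) -> np.ma.MaskedArray:
        """Masked-array view with missing entries masked out."""
        return np.ma.masked_array(self.values, mask=self.mask == 0)

    def missing_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())

    def drop_empty_features(self) -> tuple["IntensityMatrix", int]:
        """Remove features with no detected value; return (matrix, n_dropped)."""
        keep = self.mask.sum(axis=1) > 0
        n_dropped = int((~keep).sum())
        sub = IntensityMatrix(
            self.values[keep],
            self.mask[keep],
            [f for f, k in zip(self.feature_ids, keep) if k],
            list(self.sample_ids),
        )
        return sub, n_dropped


@dataclass
class FeatureSummary:
    """Per-feature detection counts and observed-intensity moments.

    ``ybar_obs`` is NaN when a feature has no detected value and ``s2`` is
    NaN when fewer than two; ``s2_moderated`` is always positive once
    moderation has been applied (features with no residual information get
    the prior value ``s2_prior``).
    """

    d: np.ndarray              # detected count per feature
    n: int                     # number of samples
    ybar_obs: np.ndarray       # mean of observed log2 intensities
    s2: np.ndarray             # sample variance of observed values
    s2_moderated: np.ndarray
    df_resid: np.ndarray       # residual df behind each s2
    df_prior: float
    s2_prior: float
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.d.shape[0]

    @property
    def informative(self) -> np.ndarray:
        """Features usable as regression rows (at least one detection)."""
        return self.d >= 1


def _trigamma_inverse(x: float) -> float:
    # Newton iterations on trigamma(y) = x, following the standard
    # monotone-convergent scheme started from the large/small-x asymptotes.
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray, df_resid: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Assumes a scaled-inverse-chi-square prior ``s2_prior * df_prior / X²``
    for the true variances and estimates ``(df_prior, s2_prior)`` by moment
    matching on the log sample variances: under the model,
    ``log s2_i - log sigma2_i`` is a log-F deviate whose mean and variance
    are digamma/trigamma expressions in the degrees of freedom.  The
    posterior mean variance is the usual precision-weighted combination

        s2_mod = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid).

    Returns ``(s2_moderated, df_prior, s2_prior)``.  Features with zero
    residual df receive the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    ok = (df_resid > 0) & np.isfinite(s2) & (s2 >= 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive residual df and variance")
    med = np.median(s2[ok])
    if med == 0:
        med = 1.0
    # exact zeros (constant observed values) are offset, not dropped
    s2 = np.where(ok, np.maximum(s2, 1e-5 * med), s2)
    z = np.log(s2[ok])
    dfo = df_resid[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    resid_var = evar - float(np.mean(special.polygamma(1, dfo / 2.0)))
    if resid_var > 0:
        df_prior = 2.0 * _trigamma_inverse(resid_var)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        # Observed log-variances are no more dispersed than sampling noise
        # alone: the prior is effectively infinitely concentrated and its
        # scale reduces to the plain average sample variance.
        df_prior = np.inf
        s2_prior = float(np.mean(s2[ok]))
    if np.isinf(df_prior):
        s2_mod = np.full(s2.shape, s2_prior)
    else:
        dfr = np.where(df_resid > 0, df_resid, 0.0)
        s2c = np.where(ok, s2, 0.0)
        s2_mod = (df_prior * s2_prior + dfr * s2c) / (df_prior + dfr)
    return s2_mod, float(df_prior), s2_prior


def summarize_features(data: IntensityMatrix) -> FeatureSummary:
    """Per-feature detection counts, observed means/variances, moderated variances.

    Features detected in no sample are retained (their absence is what the
    zero-truncated likelihood corrects for) but flagged by ``d == 0`` and
    excluded from regression rows downstream.

    Raises
    ------
    ValueError
        If the matrix contains no detected values at all.
    """
    d = data.mask.sum(axis=1).astype(int)
    if d.sum() == 0:
        raise ValueError("no detected values in the matrix")
    m = data.masked
    with np.errstate(invalid="ignore"):
        ybar = np.asarray(m.mean(axis=1).filled(np.nan), dtype=float)
        s2 = np.asarray(m.var(axis=1, ddof=1).filled(np.nan), dtype=float)
    s2 = np.where(d >= 2, s2, np.nan)
    df_resid = np.maximum(d - 1, 0).astype(float)
    s2_mod, df_prior, s2_prior = squeeze_variances(
        np.where(np.isnan(s2), 0.0, s2), df_resid
    )
    s2_mod = np.where(d >= 1, s2_mod, np.nan)
    return FeatureSummary(
        d=d,
        n=data.n_samples,
        ybar_obs=ybar,
        s2=s2,
        s2_moderated=s2_mod,
        df_resid=df_resid,
        df_prior=df_prior,
        s2_prior=s2_prior,
        feature_ids=list(data.feature_ids),
    )
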