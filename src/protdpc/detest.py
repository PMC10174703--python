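"""Two-group differential expression with and without a missingness model.

Two pipelines are implemented:

* a moderated-t test on the observed values only (empirical-Bayes variance
  shrinkage, augmented degrees of freedom) — the standard reference
  analysis, which simply drops missing entries feature-wise;
* a likelihood-ratio test that keeps every sample in the likelihood: an
  observed value contributes a normal density term and a missing value
  contributes its marginal probability under the detection probability
  curve,

      p(d=0; mu, sigma2) = Int N(y; mu, sigma2) * (1 - logistic(b0 + b1*y)) dy,

  evaluated by Gauss-Hermite quadrature.  The DPC coefficients are global
  plug-ins (estimated once on the whole matrix); per-feature variances are
  moderated and held fixed while group means are profiled out by a damped
  Newton iteration, vectorised across features.  The statistic
  2*(l_alt - l_null) is referred to chi-square with 1 df.

Benjamini-Hochberg adjustment controls the FDR across tested features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_expit, roots_hermite
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix, squeeze_variances


__all__ = [
    "DEResults",
    "DifferentialExpression",
    "moderated_t_test",
    "dpc_lrt",
    "missing_loglik",
    "benjamini_hochberg",
    "evaluate_de",
]

_DEFAULT_NODES = 32


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are excluded and propagated."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def missing_loglik(mu, sigma2, beta0: float, beta1: float,
                   n_nodes: int = _DEFAULT_NODES):
    """log p(d=0; mu, sigma2) under the DPC, by Gauss-Hermite quadrature.

    Vectorised over ``mu`` (and broadcastable ``sigma2``).  With the change
    of variable y = mu + sqrt(2*sigma2)*x the integral becomes a weighted
    sum of logistic tail probabilities at the Hermite nodes; the sum is
    accumulated in log space.  Degenerate ``sigma2 = 0`` collapses to the
    pointwise missingness probability at ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be non-negative")
    x, w = roots_hermite(n_nodes)
    scale = np.sqrt(2.0 * sigma2)
    y = mu[..., None] + scale[..., None] * x if mu.ndim else mu + scale * x
    logterms = np.log(w) + log_expit(-(beta0 + beta1 * y))
    out = _logsumexp_last(logterms) - 0.5 * np.log(np.pi)
    if np.any(sigma2 == 0):
        degenerate = log_expit(-(beta0 + beta1 * mu))
        out = np.where(sigma2 == 0, degenerate, out)
    return out if out.ndim else float(out)


def _logsumexp_last(a):
    amax = np.max(a, axis=-1, keepdims=True)
    return np.squeeze(amax, -1) + np.log(np.sum(np.exp(a - amax), axis=-1))


@dataclass
class DEResults:
    """Per-feature differential-expression results.

    ``table`` columns: feature_id, effect (log2 fold change, group 2 minus
    group 1), stat, p_value, fdr, n_obs_g1, n_obs_g2, method.
    """

    table: pd.DataFrame
    method: str
    df_prior: float = np.nan
    s2_prior: float = np.nan

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    @property
    def fdr(self) -> np.ndarray:
        return self.table["fdr"].to_numpy()

    def significant(self, threshold: float = 0.05) -> np.ndarray:
        fdr = self.fdr
        return np.where(np.isfinite(fdr), fdr < threshold, False)

    def summary(self, threshold: float = 0.05) -> str:
        n = len(self.table)
        tested = int(np.isfinite(self.p_values).sum())
        sig = int(self.significant(threshold).sum())
        lines = [
            f"Differential expression ({self.method})",
            "=" * 46,
            f"features:            {n}",
            f"tested:              {tested}",
            f"significant (BH<{threshold:g}): {sig}",
        ]
        if np.isfinite(self.df_prior):
            lines.append(f"variance prior df:   {self.df_prior:.2f}")
        if np.isfinite(self.s2_prior):
            lines.append(f"variance prior s2:   {self.s2_prior:.4f}")
        return "\n".join(lines)


class DifferentialExpression:
    """Two-group differential-expression model over an intensity matrix.

    Parameters
    ----------
    data
        Feature-by-sample :class:`IntensityMatrix`.
    groups
        Per-sample labels with exactly two levels.
    """

    def __init__(self, data: IntensityMatrix, groups):
        groups = np.asarray(groups)
        if groups.shape[0] != data.n_samples:
            raise ValueError("groups length must equal the number of samples")
        levels = np.unique(groups)
        if len(levels) != 2:
            raise ValueError("exactly two group levels required")
        self.data = data
        self.g1 = groups == levels[0]
        self.g2 = groups == levels[1]
        self.levels = levels
        self._prepare()

    def _prepare(self) -> None:
        d = self.data
        mask = d.mask.astype(bool)
        vals = np.where(mask, d.values, 0.0)
        self.n1 = mask[:, self.g1].sum(axis=1)
        self.n2 = mask[:, self.g2].sum(axis=1)
        self.sum1 = vals[:, self.g1].sum(axis=1)
        self.sum2 = vals[:, self.g2].sum(axis=1)
        self.ss1 = (vals[:, self.g1] ** 2).sum(axis=1)
        self.ss2 = (vals[:, self.g2] ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.mean1 = np.where(self.n1 > 0, self.sum1 / np.maximum(self.n1, 1), np.nan)
            self.mean2 = np.where(self.n2 > 0, self.sum2 / np.maximum(self.n2, 1), np.nan)
        # residual variance from the group-means model on observed values
        rss = (
            self.ss1 - np.where(self.n1 > 0, self.sum1**2 / np.maximum(self.n1, 1), 0.0)
            + self.ss2 - np.where(self.n2 > 0, self.sum2**2 / np.maximum(self.n2, 1), 0.0)
        )
        n_groups_obs = (self.n1 > 0).astype(int) + (self.n2 > 0).astype(int)
        self.df_resid = np.maximum(self.n1 + self.n2 - n_groups_obs, 0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.s2 = np.where(self.df_resid > 0, rss / np.maximum(self.df_resid, 1), 0.0)
        self.s2 = np.clip(self.s2, 0.0, None)  # guard tiny negative round-off
        self.s2_mod, self.df_prior, self.s2_prior = squeeze_variances(
            self.s2, self.df_resid
        )

    def _base_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.data.feature_ids,
                "effect": self.mean2 - self.mean1,
                "n_obs_g1": self.n1,
                "n_obs_g2": self.n2,
            }
        )

    def fit_moderated_t(self) -> DEResults:
        """Moderated-t test on observed values (missing entries dropped).

        Testable features need at least one observation in each group and
        three overall; others get NA statistics.
        """
        testable = (self.n1 >= 1) & (self.n2 >= 1) & (self.n1 + self.n2 >= 3)
        if testable.sum() < 2:
            raise ValueError("fewer than 2 testable features")
        stat = np.full(self.data.n_features, np.nan)
        pval = np.full(self.data.n_features, np.nan)
        se = np.sqrt(self.s2_mod * (1.0 / np.maximum(self.n1, 1)
                                    + 1.0 / np.maximum(self.n2, 1)))
        # augmented df, capped at the pooled residual df across features
        df_total = np.minimum(self.df_resid + self.df_prior, self.df_resid.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (self.mean2 - self.mean1) / se
        stat[testable] = t[testable]
        pval[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df_total[testable])
        tab = self._base_table()
        tab["stat"] = stat
        tab["p_value"] = pval
        tab["fdr"] = benjamini_hochberg(pval)
        tab["method"] = "moderated_t"
        tab = tab[["feature_id", "effect", "stat", "p_value", "fdr",
                   "n_obs_g1", "n_obs_g2", "method"]]
        return DEResults(tab, "moderated_t", self.df_prior, self.s2_prior)

    def fit_dpc_lrt(self, dpc, n_nodes: int = _DEFAULT_NODES,
                    single_group_features: bool = False) -> DEResults:
        """DPC likelihood-ratio test keeping missing values in the likelihood.

        ``dpc`` is ``(beta0, beta1)`` (or an object with a ``beta``
        attribute), treated as known.  By default a feature is testable
        when each group has at least one observed value; missing entries
        then still contribute their marginal probability.  With
        ``single_group_features=True`` features observed in only one group
        are tested too, taking the empty group's likelihood supremum (the
        detection pattern is explained perfectly in the low-intensity
        limit, so that supremum is 0); note the chi-square(1) reference is
        anti-conservative for those boundary features.  LR statistics are
        referred to chi-square with 1 df.
        """
        beta = getattr(dpc, "beta", dpc)
        beta0, beta1 = float(beta[0]), float(beta[1])
        if beta1 < 0:
            raise ValueError("dpc slope must be non-negative")
        m = self.data.n_features
        k1, k2 = int(self.g1.sum()), int(self.g2.sum())
        miss1 = k1 - self.n1
        miss2 = k2 - self.n2
        if single_group_features:
            testable = (self.n1 + self.n2) >= 1
        else:
            testable = (self.n1 >= 1) & (self.n2 >= 1)
        sigma2 = np.clip(self.s2_mod, 1e-10, None)

        x, w = roots_hermite(n_nodes)
        logw = np.log(w)

        def group_loglik_parts(mu, nobs, ssum, ss, nmiss, s2):
            """(loglik, dloglik, d2loglik) of one group's terms at mu (vectors)."""
            obs_ll = (-0.5 * nobs * np.log(2 * np.pi * s2)
                      - (ss - 2 * ssum * mu + nobs * mu**2) / (2 * s2))
            obs_d1 = (ssum - nobs * mu) / s2
            obs_d2 = -nobs / s2
            has_miss = nmiss > 0
            z = -(beta0 + beta1 * (mu[:, None] + np.sqrt(2 * s2)[:, None] * x))
            lt = logw + log_expit(z)
            logP0 = _logsumexp_last(lt) - 0.5 * np.log(np.pi)
            sig = np.exp(log_expit(z))
            P0 = np.exp(logP0)
            t1 = np.exp(lt)  # w * sigma(z)
            dP0 = -(beta1) * np.sum(t1 * (1 - sig), axis=-1) / np.sqrt(np.pi)
            d2P0 = (beta1**2) * np.sum(t1 * (1 - sig) * (1 - 2 * sig), axis=-1) / np.sqrt(np.pi)
            with np.errstate(divide="ignore", invalid="ignore"):
                dlog = np.where(P0 > 0, dP0 / np.maximum(P0, 1e-300), 0.0)
                d2log = np.where(P0 > 0,
                                 d2P0 / np.maximum(P0, 1e-300) - dlog**2, 0.0)
            mis_ll = np.where(has_miss, nmiss * logP0, 0.0)
            mis_d1 = np.where(has_miss, nmiss * dlog, 0.0)
            mis_d2 = np.where(has_miss, nmiss * d2log, 0.0)
            return obs_ll + mis_ll, obs_d1 + mis_d1, obs_d2 + mis_d2

        def profile(nobs_list, ssum_list, ss_list, nmiss_list, s2, mu0):
            """Maximise the summed group terms over a single mean, damped Newton."""
            mu = mu0.copy()
            for _ in range(100):
                lls, d1s, d2s = _eval(nobs_list, ssum_list, ss_list, nmiss_list, s2, mu)
                step = np.where(d2s < -1e-12, -d1s / d2s, 0.0)
                step = np.clip(step, -2.0, 2.0)
                mu = mu + step
                if np.max(np.abs(step)) < 1e-10:
                    break
            lls, _, _ = _eval(nobs_list, ssum_list, ss_list, nmiss_list, s2, mu)
            return mu, lls

        def _eval(nobs_list, ssum_list, ss_list, nmiss_list, s2, mu):
            lls = d1s = d2s = None
            for nobs, ssum, ss, nmiss in zip(nobs_list, ssum_list, ss_list, nmiss_list):
                a, b, c = group_loglik_parts(mu, nobs, ssum, ss, nmiss, s2)
                lls = a if lls is None else lls + a
                d1s = b if d1s is None else d1s + b
                d2s = c if d2s is None else d2s + c
            return lls, d1s, d2s

        nt = testable
        s2t = sigma2[nt]
        n1, n2 = self.n1[nt].astype(float), self.n2[nt].astype(float)
        su1, su2 = self.sum1[nt], self.sum2[nt]
        ss1, ss2 = self.ss1[nt], self.ss2[nt]
        m1, m2 = miss1[nt].astype(float), miss2[nt].astype(float)
        grand_mean = np.where(n1 + n2 > 0, (su1 + su2) / np.maximum(n1 + n2, 1), 0.0)

        # null: one shared mean over both groups' observed + missing terms
        mu0, ll_null = profile([n1, n2], [su1, su2], [ss1, ss2], [m1, m2],
                               s2t, grand_mean)
        # alternative: each group's mean maximised separately; a group with
        # no observed value attains sup m*log P0 = 0 in the mu -> -inf limit
        mean1 = np.where(n1 > 0, su1 / np.maximum(n1, 1), grand_mean)
        mean2 = np.where(n2 > 0, su2 / np.maximum(n2, 1), grand_mean)
        mu1, ll1 = profile([n1], [su1], [ss1], [m1], s2t, mean1)
        mu2, ll2 = profile([n2], [su2], [ss2], [m2], s2t, mean2)
        ll1 = np.where(n1 > 0, ll1, 0.0)
        ll2 = np.where(n2 > 0, ll2, 0.0)
        lr = 2.0 * (ll1 + ll2 - ll_null)
        bad = lr < -1e-8
        if np.any(bad):
            warnings.warn(f"{int(bad.sum())} features with negative LR statistic; "
                          "set to NA")
        lr = np.where(bad, np.nan, np.clip(lr, 0.0, None))
        pv = stats.chi2.sf(lr, df=1)

        stat = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        eff = np.full(m, np.nan)
        stat[nt] = lr
        pval[nt] = pv
        effect = np.where((n1 > 0) & (n2 > 0), mu2 - mu1, np.nan)
        eff[nt] = effect
        tab = self._base_table()
        tab["effect"] = eff
        tab["stat"] = stat
        tab["p_value"] = pval
        tab["fdr"] = benjamini_hochberg(pval)
        tab["method"] = "dpc_lrt"
        tab = tab[["feature_id", "effect", "stat", "p_value", "fdr",
                   "n_obs_g1", "n_obs_g2", "method"]]
        return DEResults(tab, "dpc_lrt", self.df_prior, self.s2_prior)


def moderated_t_test(data: IntensityMatrix, groups) -> DEResults:
    """Reference moderated-t pipeline on observed values only."""
    return DifferentialExpression(data, groups).fit_moderated_t()


def dpc_lrt(data: IntensityMatrix, groups, dpc, n_nodes: int = _DEFAULT_NODES,
            single_group_features: bool = False) -> DEResults:
    """DPC likelihood-ratio test with plug-in global DPC coefficients."""
    return DifferentialExpression(data, groups).fit_dpc_lrt(
        dpc, n_nodes=n_nodes, single_group_features=single_group_features)


def evaluate_de(results, de_labels, threshold: float = 0.05) -> dict:
    """True-positive rate and empirical FDR at an FDR threshold.

    ``results`` may be one :class:`DEResults` or a list (with matching
    list of label vectors) whose rates are averaged.  TPR is the fraction
    of truly DE features called; FDR is false discoveries over
    max(1, discoveries).
    """
    if isinstance(results, (list, tuple)):
        if not isinstance(de_labels, (list, tuple)) or len(results) != len(de_labels):
            raise ValueError("results and de_labels lists must align")
        evals = [evaluate_de(r, l, threshold) for r, l in zip(results, de_labels)]
        return {
            "tpr": float(np.mean([e["tpr"] for e in evals])),
            "fdr": float(np.mean([e["fdr"] for e in evals])),
            "n_true_positives": float(np.mean([e["n_true_positives"] for e in evals])),
            "n_discoveries": float(np.mean([e["n_discoveries"] for e in evals])),
            "n_replicates": len(evals),
        }
    labels = np.asarray(de_labels)
    if labels.shape[0] != len(results.table):
        raise ValueError("de_labels are misaligned with the result table")
    called = results.significant(threshold)
    is_de = labels != 0
    tp = int(np.sum(called & is_de))
    fp = int(np.sum(called & ~is_de))
    n_called = int(called.sum())
    return {
        "tpr": tp / max(1, int(is_de.sum())),
        "fdr": fp / max(1, n_called),
        "n_true_positives": tp,
        "n_discoveries": n_called,
        "n_replicates": 1,
    }
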