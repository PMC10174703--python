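"""Detection probability curve (DPC) estimation.

A DPC relates the probability that an intensity is detected (non-missing)
to log2 intensity.  Empirically the curve is summarised by logit regression
splines of the per-feature detection proportion on the average observed
log2 intensity, fitted by maximum likelihood under the zero-truncated
binomial distribution (features missing everywhere cannot appear in the
data, and the truncation corrects for their absence).  Three variants are
provided:

* logit splines with 1, 3 or 5 degrees of freedom (df=1 is the plain
  logit-linear curve), plus a deviance decomposition across df blocks;
* the capped logit-linear model ``p = alpha * logistic(b0 + b1*ybar)``
  whose asymptote ``alpha`` measures intensity-independent missingness;
* the bias-corrected logit-linear DPC on *underlying* intensity, which
  replaces the conditional linear predictor by the marginal log-odds

      logit p_i = b0 + b1*mu_obs,i - (1/2) * b1^2 * sigma2_obs,i,

  with ``mu_obs`` estimated by the observed feature mean and ``sigma2_obs``
  by the empirical-Bayes moderated variance.  This removes the bias caused
  by observed means over-representing the high end of each feature's
  intensity distribution.

The module exposes a statsmodels-style :class:`DPCModel` whose ``fit``
returns a :class:`DPCResults`, plus thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .matrix import FeatureSummary, IntensityMatrix, summarize_features
from .ztbinom import log1m_pow, ztbinom_logpmf

__all__ = [
    "SplineBasisSpec",
    "DPCModel",
    "DPCResults",
    "fit_logit_spline",
    "fit_capped_logit",
    "fit_dpc",
    "deviance_explained",
]

_P_CLIP = 1e-12  # probability clamp for likelihood evaluation
_ALPHA_LOGIT_CAP = 13.8  # expit(13.8) ~ 1 - 1e-6; treat as the alpha=1 boundary


@dataclass(frozen=True)
class SplineBasisSpec:
    """Natural cubic spline basis specification for the logit-detection fit.

    ``df`` counts the non-intercept basis columns.  df=1 is a plain linear
    term; df>=2 uses the truncated-power natural-spline construction with
    ``df - 1`` interior knots (linear beyond the boundary knots).
    """

    df: int
    knots: tuple[float, ...] = ()
    boundary_knots: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.df == 1 and self.knots:
            raise ValueError("df=1 admits no interior knots")
        if self.boundary_knots is not None:
            lo, hi = self.boundary_knots
            if not lo < hi:
                raise ValueError("boundary knots must be increasing")
            ks = np.asarray(self.knots)
            if len(ks) and (np.any(np.diff(ks) <= 0) or ks.min() <= lo or ks.max() >= hi):
                raise ValueError("interior knots must be sorted strictly inside boundary knots")

    @classmethod
    def from_data(cls, x: np.ndarray, df: int) -> "SplineBasisSpec":
        """Place df-1 interior knots at equal-count quantiles of ``x``."""
        x = np.asarray(x, dtype=float)
        if df == 1:
            return cls(df=1)
        probs = np.arange(1, df) / df
        knots = tuple(np.quantile(x, probs))
        return cls(df=df, knots=knots, boundary_knots=(float(x.min()), float(x.max())))

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the (len(x), df) basis matrix (no intercept column)."""
        x = np.asarray(x, dtype=float)
        if self.df == 1:
            return x[:, None]
        if self.boundary_knots is None:
            raise ValueError("boundary knots required for df >= 2")
        xi = np.asarray([self.boundary_knots[0], *self.knots, self.boundary_knots[1]])
        K = len(xi)

        def d(k):  # (x - xi_k)_+^3 - (x - xi_{K-1})_+^3, scaled
            return (
                np.maximum(x - xi[k], 0.0) ** 3 - np.maximum(x - xi[K - 1], 0.0) ** 3
            ) / (xi[K - 1] - xi[k])

        cols = [x]
        dK2 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK2)
        return np.column_stack(cols)


@dataclass
class DPCResults:
    """Fitted detection probability curve.

    Attributes
    ----------
    beta
        Coefficients (intercept first).  For spline fits the remaining
        entries multiply the natural-spline basis columns; for
        ``x_kind='underlying-mean'`` there are exactly two entries
        ``(b0, b1)``.
    alpha
        Detection asymptote; 1.0 unless the capped model was fitted.
    loglik
        Maximised zero-truncated binomial log-likelihood.
    x_kind
        'observed-mean' or 'underlying-mean'.
    """

    beta: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    x_kind: str
    n: int
    n_features_used: int
    spec: SplineBasisSpec | None = None
    alpha_at_boundary: bool = False
    bse: np.ndarray | None = None
    deviance_table: pd.DataFrame | None = None
    model: "DPCModel | None" = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return self.beta

    def predict(self, x: np.ndarray, sigma2: np.ndarray | float = 0.0) -> np.ndarray:
        """Detection probability at mean intensity ``x``.

        For underlying-mean fits ``sigma2`` enters through the marginal
        log-odds correction; for observed-mean fits it is ignored unless
        nonzero values are supplied (they are then applied the same way,
        which collapses to no correction for spline fits only when df=1).
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.x_kind == "underlying-mean":
            b0, b1 = self.beta
            eta = b0 + b1 * x - 0.5 * b1**2 * np.asarray(sigma2, dtype=float)
        else:
            X = self.spec.basis(x)
            eta = self.beta[0] + X @ self.beta[1:]
        return self.alpha * expit(eta)

    def summary(self) -> str:
        lines = [
            "Detection probability curve (zero-truncated binomial ML)",
            "=" * 58,
            f"x variable:        {self.x_kind}",
            f"features used:     {self.n_features_used}   samples: {self.n}",
            f"log-likelihood:    {self.loglik:.4f}",
            f"converged:         {self.converged}",
        ]
        names = ["beta0"] + [f"beta{i}" for i in range(1, len(self.beta))]
        lines.append("-" * 58)
        lines.append(f"{'term':<10}{'coef':>12}" + ("" if self.bse is None else f"{'std err':>12}"))
        for i, nm in enumerate(names):
            row = f"{nm:<10}{self.beta[i]:>12.4f}"
            if self.bse is not None:
                row += f"{self.bse[i]:>12.4f}"
            lines.append(row)
        if self.alpha != 1.0 or self.alpha_at_boundary:
            note = " (boundary)" if self.alpha_at_boundary else ""
            lines.append(f"{'alpha':<10}{self.alpha:>12.4f}{note}")
        if self.deviance_table is not None:
            lines.append("-" * 58)
            lines.append("Deviance explained (%):")
            lines.append(self.deviance_table.to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "beta": [float(b) for b in self.beta],
            "alpha": float(self.alpha),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "x_kind": self.x_kind,
            "n": int(self.n),
            "n_features_used": int(self.n_features_used),
        }
        if self.deviance_table is not None:
            out["deviance_table"] = self.deviance_table.to_dict(orient="records")
        return out


def _ztb_loglik_grad_eta(d, n, p):
    """Log-likelihood and d(loglik)/d(eta) summand for p = expit(eta) rows."""
    p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    ll = float(np.sum(ztbinom_logpmf(d, n, p)))
    # d/d(eta) log ZB = d_i - n p / (1 - q^n), q = 1 - p
    trunc = np.exp(log1m_pow(n, np.log1p(-p)))
    g = d - n * p / trunc
    return ll, g


class DPCModel:
    """Detection-probability-curve model for an intensity matrix.

    Parameters
    ----------
    data
        An :class:`IntensityMatrix` or a precomputed :class:`FeatureSummary`.

    Examples
    --------
    >>> model = DPCModel(matrix)            # doctest: +SKIP
    >>> res = model.fit(df=1)               # observed-mean logit-linear
    >>> res_u = model.fit(underlying=True)  # bias-corrected DPC
    >>> print(res_u.summary())
    """

    def __init__(self, data: IntensityMatrix | FeatureSummary):
        if isinstance(data, IntensityMatrix):
            self.summary_ = summarize_features(data)
        elif isinstance(data, FeatureSummary):
            self.summary_ = data
        else:
            raise TypeError("data must be an IntensityMatrix or FeatureSummary")
        s = self.summary_
        use = s.informative
        self._d = s.d[use].astype(float)
        self._n = int(s.n)
        self._x = s.ybar_obs[use]
        self._v = s.s2_moderated[use]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "DPCModel":
        """Build from a wide feature-by-sample DataFrame (NaN = missing)."""
        values = frame.to_numpy(dtype=float)
        mask = np.isfinite(values)
        mat = IntensityMatrix(values, mask, [str(i) for i in frame.index],
                              [str(c) for c in frame.columns])
        return cls(mat)

    # ---- internal fitting machinery -------------------------------------

    def _check_not_saturated(self) -> None:
        if np.all(self._d == self._n):
            raise ValueError("detection saturated: every feature detected in all samples")

    def _start_values(self, X: np.ndarray) -> np.ndarray:
        # Untruncated logistic regression of d/n on the basis as starting point.
        import statsmodels.api as sm

        endog = np.column_stack([self._d, self._n - self._d])
        exog = np.column_stack([np.ones(len(X)), X])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(maxiter=50)
            beta = np.asarray(glm.params, dtype=float)
            if np.all(np.isfinite(beta)):
                return beta
        except Exception:
            pass
        prop = np.clip(self._d.mean() / self._n, 0.01, 0.99)
        beta = np.zeros(X.shape[1] + 1)
        beta[0] = logit(prop)
        return beta

    def _maximize(self, negloglik_grad, theta0, bounds=None):
        res = optimize.minimize(
            negloglik_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not res.success and "ABNORMAL" not in str(res.message):
            warnings.warn(f"DPC optimizer did not converge: {res.message}")
        return res

    def _bse(self, negloglik_grad, theta):
        from statsmodels.tools.numdiff import approx_hess1

        try:
            H = approx_hess1(theta, lambda t: negloglik_grad(t)[0])
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            return se
        except np.linalg.LinAlgError:
            return None

    # ---- public fits -----------------------------------------------------

    def fit(self, df: int = 1, capped: bool = False, underlying: bool = False,
            spec: SplineBasisSpec | None = None, alpha_fixed: float | None = None,
            start: np.ndarray | None = None, compute_bse: bool = True) -> DPCResults:
        """Fit a DPC variant; exactly one of the spline/capped/underlying paths.

        ``df`` selects the spline flexibility for the observed-mean fit;
        ``capped=True`` adds the asymptote parameter (df must be 1);
        ``underlying=True`` fits the bias-corrected logit-linear curve on
        underlying intensity.
        """
        if underlying:
            if capped or df != 1:
                raise ValueError("the underlying-intensity DPC is logit-linear only")
            return self._fit_underlying(start=start, compute_bse=compute_bse)
        if capped:
            if df != 1:
                raise ValueError("the capped model is logit-linear only")
            return self._fit_capped(alpha_fixed=alpha_fixed, compute_bse=compute_bse)
        return self._fit_spline(df=df, spec=spec, compute_bse=compute_bse)

    def _fit_spline(self, df: int = 1, spec: SplineBasisSpec | None = None,
                    intercept_only: bool = False, compute_bse: bool = True) -> DPCResults:
        self._check_not_saturated()
        d, n = self._d, self._n
        if intercept_only:
            X = np.ones((len(d), 1))
            spec = None
        else:
            if spec is None:
                spec = SplineBasisSpec.from_data(self._x, df)
            B = spec.basis(self._x)
            if len(d) < B.shape[1] + 1:
                raise ValueError("need at least df+1 informative features")
            X = np.column_stack([np.ones(len(d)), B])

        # d(eta)/d(beta) = X and d(loglik)/d(eta) = g, so grad = X' g
        def nll(beta):
            eta = X @ beta
            p = expit(eta)
            ll, g = _ztb_loglik_grad_eta(d, n, p)
            return -ll, -(X.T @ g)

        theta0 = self._start_values(X[:, 1:]) if not intercept_only else \
            np.array([logit(np.clip(d.mean() / n, 0.01, 0.99))])
        res = self._maximize(nll, theta0)
        bse = self._bse(nll, res.x) if compute_bse else None
        return DPCResults(
            beta=res.x, alpha=1.0, loglik=-res.fun, converged=bool(res.success),
            x_kind="observed-mean", n=n, n_features_used=len(d), spec=spec,
            bse=bse, model=self,
        )

    def _fit_capped(self, alpha_fixed: float | None = None,
                    compute_bse: bool = True) -> DPCResults:
        self._check_not_saturated()
        d, n = self._d, self._n
        x = self._x
        if alpha_fixed is not None:
            if not 0 < alpha_fixed <= 1:
                raise ValueError("alpha must be in (0, 1]")
            base = self._fit_spline(df=1, compute_bse=compute_bse) if alpha_fixed == 1.0 else None
            if base is not None:
                base.alpha = 1.0
                return base

        def nll(theta):
            b0, b1, a_logit = theta
            alpha = expit(a_logit)
            eta = b0 + b1 * x
            s = expit(eta)
            p = np.clip(alpha * s, _P_CLIP, 1 - _P_CLIP)
            ll = float(np.sum(ztbinom_logpmf(d, n, p)))
            # d ll / d p
            q = 1 - p
            trunc = np.exp(log1m_pow(n, np.log1p(-p)))
            dldp = d / p - (n - d) / q - n * q ** (n - 1) / trunc
            gb0 = np.sum(dldp * alpha * s * (1 - s))
            gb1 = np.sum(dldp * alpha * s * (1 - s) * x)
            ga = np.sum(dldp * s * alpha * (1 - alpha))
            return -ll, -np.array([gb0, gb1, ga])

        lin = self._fit_spline(df=1, compute_bse=False)
        theta0 = np.array([lin.beta[0], lin.beta[1], logit(0.99)])
        bounds = [(None, None), (None, None), (None, _ALPHA_LOGIT_CAP)]
        res = self._maximize(nll, theta0, bounds=bounds)
        at_boundary = res.x[2] >= _ALPHA_LOGIT_CAP - 1e-6
        if at_boundary:
            out = self._fit_spline(df=1, compute_bse=compute_bse)
            out.alpha = 1.0
            out.alpha_at_boundary = True
            return out
        bse = self._bse(nll, res.x) if compute_bse else None
        return DPCResults(
            beta=res.x[:2], alpha=float(expit(res.x[2])), loglik=-res.fun,
            converged=bool(res.success), x_kind="observed-mean", n=n,
            n_features_used=len(d), spec=SplineBasisSpec(df=1),
            alpha_at_boundary=False,
            bse=bse[:2] if bse is not None else None, model=self,
        )

    def _fit_underlying(self, start: np.ndarray | None = None,
                        compute_bse: bool = True) -> DPCResults:
        self._check_not_saturated()
        d, n = self._d, self._n
        x, v = self._x, np.where(np.isfinite(self._v), self._v, 0.0)
        if len(d) < 2:
            raise ValueError("need at least 2 informative features")

        def nll(beta):
            b0, b1 = beta
            eta = b0 + b1 * x - 0.5 * b1**2 * v
            p = expit(eta)
            ll, g = _ztb_loglik_grad_eta(d, n, p)
            return -ll, -np.array([np.sum(g), np.sum(g * (x - b1 * v))])

        if start is None:
            lin = self._fit_spline(df=1, compute_bse=False)
            start = lin.beta.copy()
        res = self._maximize(nll, np.asarray(start, dtype=float))
        bse = self._bse(nll, res.x) if compute_bse else None
        return DPCResults(
            beta=res.x, alpha=1.0, loglik=-res.fun, converged=bool(res.success),
            x_kind="underlying-mean", n=n, n_features_used=len(d),
            bse=bse, model=self,
        )

    def deviance_decomposition(self) -> pd.DataFrame:
        """Percentage of total deviance explained by each spline df block.

        Total deviance is twice the log-likelihood gap between the df=5
        spline and the intercept-only model; the rows split it into the
        linear share and the increments from df=3 and df=5.
        """
        fit0 = self._fit_spline(intercept_only=True, compute_bse=False)
        fits = {df: self._fit_spline(df=df, compute_bse=False) for df in (1, 3, 5)}
        return deviance_explained(self.summary_, fits[1], fits[3], fits[5], fit0=fit0)


def deviance_explained(summary: FeatureSummary, fit1: DPCResults, fit3: DPCResults,
                       fit5: DPCResults, fit0: DPCResults | None = None) -> pd.DataFrame:
    """Deviance-explained table from nested df=1/3/5 spline fits.

    The fits must come from the same rows (same feature count and sample
    size); an intercept-only fit is computed from ``summary`` if not given.
    """
    fits = (fit1, fit3, fit5)
    dfs = tuple(0 if f.spec is None else f.spec.df for f in fits)
    if dfs != (1, 3, 5):
        raise ValueError("expected fits with spline df 1, 3 and 5 in order")
    if len({f.n_features_used for f in fits}) != 1 or len({f.n for f in fits}) != 1:
        raise ValueError("fits are not nested: differing rows or sample size")
    if any(f.x_kind != "observed-mean" for f in fits):
        raise ValueError("deviance decomposition applies to observed-mean spline fits")
    if fit0 is None:
        fit0 = DPCModel(summary)._fit_spline(intercept_only=True, compute_bse=False)
    ll0, ll1, ll3, ll5 = (f.loglik for f in (fit0, fit1, fit3, fit5))
    total = 2.0 * (ll5 - ll0)
    dev = np.array([2.0 * (ll1 - ll0), 2.0 * (ll3 - ll1), 2.0 * (ll5 - ll3)])
    pct = 100.0 * dev / total if total > 0 else np.full(3, np.nan)
    return pd.DataFrame(
        {
            "source": ["Linear", "Non-linear 2-3", "Non-linear 4-5"],
            "deviance": dev,
            "pct_explained": pct,
        }
    )


# ---- functional wrappers over the model object ---------------------------

def fit_logit_spline(summary: FeatureSummary, spec: SplineBasisSpec | int = 1) -> DPCResults:
    """Logit-spline DPC on observed means under the zero-truncated binomial."""
    if isinstance(spec, int):
        return DPCModel(summary).fit(df=spec)
    return DPCModel(summary).fit(df=spec.df, spec=spec)


def fit_capped_logit(summary: FeatureSummary, alpha_fixed: float | None = None) -> DPCResults:
    """Capped logit-linear DPC: p = alpha * logistic(b0 + b1 * ybar_obs)."""
    return DPCModel(summary).fit(capped=True, alpha_fixed=alpha_fixed)


def fit_dpc(summary: FeatureSummary | IntensityMatrix) -> DPCResults:
    """Bias-corrected logit-linear DPC on underlying intensity (marginal log-odds)."""
    return DPCModel(summary).fit(underlying=True)
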