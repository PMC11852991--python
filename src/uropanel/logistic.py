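"""Maximum-likelihood binary logistic regression and forward stepwise selection.

:class:`BinaryLogit` is a small statsmodels-style model object: construct it
from an outcome vector and a (typically binary, dichotomized-biomarker)
design matrix, call :meth:`~BinaryLogit.fit`, and read odds ratios, Wald
confidence intervals and the log-likelihood off the returned
:class:`LogisticResults`.  Fitting is by iteratively reweighted least squares
(IRLS); complete or quasi-complete separation is detected and flagged rather
than penalized, and flagged fits report their odds ratios as unavailable.

:func:`forward_stepwise` adds, at each step, the candidate predictor with the
largest likelihood-ratio improvement, as long as its LRT p-value passes the
entry threshold; there is no removal step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "BinaryLogit",
    "LogisticResults",
    "StepwisePath",
    "forward_stepwise",
    "logit_from_counts",
    "counts_from_rates",
]

_SEPARATION_COEF = 15.0
_SEPARATION_SE = 1e3


class BinaryLogit:
    """Binary logistic regression model.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Outcome vector; must contain both classes.
    exog : array-like or DataFrame
        Predictor matrix (without intercept; one is added unless
        ``add_intercept=False``).  All-constant predictors are rejected by
        name.
    exog_names : sequence of str, optional
        Predictor names; taken from DataFrame columns when available.
    """

    def __init__(self, endog, exog, exog_names=None, add_intercept: bool = True):
        if isinstance(exog, pd.DataFrame):
            if exog_names is None:
                exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(X.shape[1])]
        if len(exog_names) != X.shape[1]:
            raise ValueError("exog_names length does not match number of predictors")
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing values must be excluded before fitting")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("outcome has a single class; logistic fit undefined")
        for j, name in enumerate(exog_names):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"predictor {name!r} is constant")
        self.endog = y
        self.exog_names = list(exog_names)
        if add_intercept:
            self.exog = np.column_stack([np.ones_like(y), X])
            self.param_names = ["intercept"] + self.exog_names
        else:
            self.exog = X
            self.param_names = list(self.exog_names)
        self.add_intercept = add_intercept

    # ------------------------------------------------------------------
    def loglike(self, params) -> float:
        eta = self.exog @ np.asarray(params, dtype=float)
        # log(1 + e^eta) computed stably
        return float(self.endog @ eta - np.logaddexp(0.0, eta).sum())

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "LogisticResults":
        """IRLS maximum likelihood.

        Converged when the deviance change drops below ``tol`` (default
        1e-8) or after ``maxiter`` iterations.  Separation is declared when
        any coefficient exceeds 15 in absolute value or a Wald SE explodes.
        """
        y, X = self.endog, self.exog
        n, p = X.shape
        beta = np.zeros(p)
        dev = -2.0 * self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            WX = X * w[:, None]
            try:
                beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
            except np.linalg.LinAlgError:
                break
            beta = beta_new
            dev_new = -2.0 * self.loglike(beta)
            if abs(dev - dev_new) < tol:
                dev = dev_new
                converged = True
                break
            dev = dev_new

        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = np.full(p, np.nan)
        separation = bool(
            np.any(np.abs(beta) > _SEPARATION_COEF)
            or np.any(~np.isfinite(bse))
            or np.any(bse > _SEPARATION_SE)
        )
        return LogisticResults(
            model=self,
            params=beta,
            bse=bse,
            cov_params=cov,
            llf=self.loglike(beta),
            deviance=dev,
            converged=converged,
            separation=separation,
            nobs=n,
        )


@dataclass
class LogisticResults:
    """Fitted logistic regression: coefficients, ORs, Wald CIs, likelihood."""

    model: BinaryLogit
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    deviance: float
    converged: bool
    separation: bool
    nobs: int

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def _predictor_slice(self) -> slice:
        return slice(1, None) if self.model.add_intercept else slice(None)

    @property
    def odds_ratios(self) -> pd.Series:
        """exp(coef) per predictor; NaN when separation was flagged."""
        sl = self._predictor_slice()
        values = np.exp(self.params[sl])
        if self.separation:
            values = np.full_like(values, np.nan)
        return pd.Series(values, index=self.model.exog_names, name="OR")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald confidence intervals on the odds-ratio scale.

        ``exp(coef +/- z * SE)`` with SE from the observed information; for a
        single binary predictor this equals the classical
        ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  Unavailable
        (all-NaN) when separation was flagged.
        """
        sl = self._predictor_slice()
        z = norm.ppf(0.5 + level / 2.0)
        if self.separation:
            k = len(self.model.exog_names)
            lo = np.full(k, np.nan)
            hi = np.full(k, np.nan)
        else:
            lo = np.exp(self.params[sl] - z * self.bse[sl])
            hi = np.exp(self.params[sl] + z * self.bse[sl])
        return pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=self.model.exog_names)

    def pvalues(self) -> pd.Series:
        sl = self._predictor_slice()
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = self.params[sl] / self.bse[sl]
        p = 2.0 * norm.sf(np.abs(zstat))
        return pd.Series(p, index=self.model.exog_names, name="p")

    def summary(self, level: float = 0.95) -> str:
        ci = self.conf_int(level)
        ors = self.odds_ratios
        pv = self.pvalues()
        lines = [
            "Binary logistic regression (IRLS maximum likelihood)",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.4f}, "
            f"deviance = {self.deviance:.4f}",
            f"  converged = {self.converged}, separation = {self.separation}",
            f"  {'predictor':<28s} {'OR':>10s} {'95% CI':>20s} {'p':>8s}",
        ]
        for name in self.model.exog_names:
            if self.separation:
                lines.append(f"  {name:<28s} {'--':>10s} {'(unavailable)':>20s} {'--':>8s}")
            else:
                lines.append(
                    f"  {name:<28s} {ors[name]:>10.3f} "
                    f"({ci.loc[name, 'ci_low']:>8.3f}-{ci.loc[name, 'ci_high']:.3f}) "
                    f"{pv[name]:>8.4f}"
                )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# 2x2 helpers
# ----------------------------------------------------------------------

def logit_from_counts(a: int, b: int, c: int, d: int) -> LogisticResults:
    """Fit the single-binary-predictor logistic model to a 2x2 table.

    ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed noncases,
    ``d`` unexposed noncases.  The MLE odds ratio equals the cross-product
    ratio ``ad / bc``.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"cell {name} must be a non-negative integer; got {v}")
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return BinaryLogit(y, x, exog_names=["exposed"]).fit()


def counts_from_rates(sens: float, spec: float, n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct (TP, FN, FP, TN) from printed sensitivity/specificity.

    Rates are proportions in [0, 1]; counts are recovered by rounding
    ``sens * n_pos`` and ``spec * n_neg`` to the nearest integer, which is
    exact whenever the printed rates came from integer confusion counts.
    """
    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    return tp, n_pos - tp, n_neg - tn, tn


# ----------------------------------------------------------------------
# Forward stepwise selection
# ----------------------------------------------------------------------

@dataclass
class StepEntry:
    predictor: str
    llf_before: float
    llf_after: float
    lrt: float
    pvalue: float


@dataclass
class StepwisePath:
    """Record of a forward stepwise selection run."""

    steps: list[StepEntry] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    entry_alpha: float = 0.05
    final_results: LogisticResults | None = None

    @property
    def loglikelihoods(self) -> list[float]:
        return [s.llf_after for s in self.steps]

    def summary(self) -> str:
        lines = [f"Forward stepwise selection (LRT entry p <= {self.entry_alpha:g})"]
        if not self.steps:
            lines.append("  (no predictor entered)")
        for i, s in enumerate(self.steps, 1):
            lines.append(
                f"  step {i}: + {s.predictor:<28s} llf {s.llf_before:.4f} -> {s.llf_after:.4f}"
                f"  LRT {s.lrt:.3f}  p {s.pvalue:.4g}"
            )
        return "\n".join(lines)


def _null_llf(y: np.ndarray) -> float:
    p = y.mean()
    n1 = y.sum()
    n0 = y.size - n1
    if p in (0.0, 1.0):
        return 0.0
    return float(n1 * np.log(p) + n0 * np.log(1.0 - p))


def forward_stepwise(
    candidates: pd.DataFrame,
    outcome,
    entry_alpha: float = 0.05,
) -> StepwisePath:
    """Forward stepwise logistic selection by likelihood-ratio improvement.

    At each step every remaining candidate is added in turn to the current
    model; the one with the largest LRT improvement enters if its chi-square
    p-value is at or below ``entry_alpha`` (and the improvement is strictly
    positive, so duplicates of entered predictors never enter).  Stops when
    no candidate qualifies.  Rows with missing values in any candidate are
    dropped once, up front.

    Parameters
    ----------
    candidates : DataFrame
        One column per candidate predictor (typically 0/1 exceedance
        indicators).  An empty frame yields an empty, valid path.
    outcome : array-like of {0, 1}
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if candidates.shape[1] == 0:
        return StepwisePath(entry_alpha=entry_alpha)
    mask = ~(np.isnan(y) | candidates.isna().any(axis=1).to_numpy())
    y = y[mask]
    cand = candidates.loc[mask]
    if y.size == 0 or y.min() == y.max():
        raise ValueError("outcome must contain both classes after dropping missing rows")

    selected: list[str] = []
    remaining = list(cand.columns)
    llf_current = _null_llf(y)
    path = StepwisePath(entry_alpha=entry_alpha)
    current_fit: LogisticResults | None = None

    while remaining:
        best = None
        for name in remaining:
            cols = selected + [name]
            try:
                fit = BinaryLogit(y, cand[cols]).fit()
            except (ValueError, np.linalg.LinAlgError):
                continue
            lrt = 2.0 * (fit.llf - llf_current)
            if best is None or lrt > best[1]:
                best = (name, lrt, fit)
        if best is None:
            break
        name, lrt, fit = best
        pvalue = float(chi2.sf(max(lrt, 0.0), df=1))
        if lrt <= 1e-10 or pvalue > entry_alpha:
            break
        selected.append(name)
        remaining.remove(name)
        path.steps.append(
            StepEntry(predictor=name, llf_before=llf_current, llf_after=fit.llf,
                      lrt=lrt, pvalue=pvalue)
        )
        llf_current = fit.llf
        current_fit = fit

    path.selected = selected
    path.final_results = current_fit
    return path
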