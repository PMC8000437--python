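"""Maximum-likelihood logistic regression with Wald inference.

A compact iteratively-reweighted-least-squares (Newton) fitter with
score-equation convergence control, per-iteration log-likelihood tracking
(monotone by step-halving), covariance from the inverse observed information,
and explicit separation diagnostics — plus crude and adjusted odds ratios for
the predictor codings of the study schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .schema import AnalysisSubset, DesignMatrix, PredictorSpec, adjuster_specs, encode

__all__ = [
    "LogisticFit",
    "OddsRatioResult",
    "SeparationWarning",
    "fit_logistic",
    "crude_or",
    "adjusted_or",
    "wald_results",
    "Z975",
]

#: Two-sided 95 % normal quantile used in all Wald confidence intervals.
Z975 = float(stats.norm.ppf(0.975))  # 1.959964...

_SCORE_TOL = 1e-8
_MAX_ITER = 100
_BETA_LIMIT = 15.0
_PROB_EPS = 1e-10


class SeparationWarning(UserWarning):
    """Emitted when a fit shows signs of (quasi-)separation."""


class RankDeficientError(ValueError):
    """Raised when the design matrix is not of full column rank."""


@dataclass
class LogisticFit:
    """Result of one ML logistic fit (intercept coefficient first)."""

    beta: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    separation: bool
    columns: list[str]
    loglik_path: list[float]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class OddsRatioResult:
    """Odds ratio with Wald 95 % CI and p-value for one design column."""

    label: tuple[str, str | None]  # (predictor, category)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    converged: bool = True
    separation: bool = False


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = np.flatnonzero(diag <= scale * max(X.shape) * np.finfo(float).eps * 10)
    if bad.size:
        names = [columns[i] for i in bad]
        raise RankDeficientError(f"design matrix rank deficient; collinear columns: {names}")


def fit_logistic(design: DesignMatrix) -> LogisticFit:
    """Fit by IRLS to score tolerance 1e-8 (max 100 iterations).

    The log-likelihood is made non-decreasing across iterations by
    step-halving.  Separation (any |beta| > 15 or fitted probability within
    1e-10 of 0/1) and non-convergence are flagged on the result and emitted
    as warnings, never silently ignored.
    """
    X, y = design.X, np.asarray(design.y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant: need at least one case and one control")
    _check_rank(X, design.columns)
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    path = [ll]
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        score = X.T @ (y - prob)
        if np.max(np.abs(score)) <= _SCORE_TOL:
            converged = True
            it -= 1
            break
        w = np.clip(prob * (1.0 - prob), 1e-12, None)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the log-likelihood monotone
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - np.log1p(np.exp(eta_c))))
            if ll_c >= ll - 1e-12:
                break
            factor *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
        prob = 1.0 / (1.0 + np.exp(-eta))
        path.append(ll)
    else:
        it = _MAX_ITER
    w = np.clip(prob * (1.0 - prob), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    # the intercept is excluded: its magnitude tracks the scale of uncentered
    # covariates, not separation
    slope = np.array([b for b, c in zip(beta, design.columns) if c != "intercept"])
    separation = bool(np.any(np.abs(slope) > _BETA_LIMIT)
                      or np.any(prob < _PROB_EPS) or np.any(prob > 1.0 - _PROB_EPS))
    if separation:
        warnings.warn(
            "possible (quasi-)separation: extreme coefficient or fitted "
            "probability; Wald intervals are unreliable", SeparationWarning,
            stacklevel=2)
    if not converged:
        warnings.warn(
            f"logistic fit did not reach score tolerance {_SCORE_TOL} "
            f"in {_MAX_ITER} iterations", SeparationWarning, stacklevel=2)
    return LogisticFit(beta=beta, cov=cov, fitted=prob, loglik=ll,
                       converged=converged, n_iter=it, separation=separation,
                       columns=list(design.columns), loglik_path=path)


def wald_results(fit: LogisticFit, design: DesignMatrix,
                 keep: set[str] | None = None) -> list[OddsRatioResult]:
    """Per-coefficient odds ratios with Wald CI/p (intercept excluded).

    ``keep`` restricts output to coefficients of the named predictors.
    """
    out = []
    se = fit.se
    for j, (pred, cat) in enumerate(design.colmap):
        if pred == "intercept":
            continue
        if keep is not None and pred not in keep:
            continue
        b, s = float(fit.beta[j]), float(se[j])
        z = b / s if s > 0 else np.inf
        with np.errstate(over="ignore"):
            out.append(OddsRatioResult(
                label=(pred, cat),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - Z975 * s)),
                ci_high=float(np.exp(b + Z975 * s)),
                p_value=float(2.0 * stats.norm.sf(abs(z))),
                beta=b, se=s,
                converged=fit.converged, separation=fit.separation))
    return out


def crude_or(table: CohortTable, subset: AnalysisSubset,
             spec: PredictorSpec) -> list[OddsRatioResult]:
    """Univariable odds ratio(s) of the tested coding."""
    design = encode(subset, spec, table)
    fit = fit_logistic(design)
    return wald_results(fit, design)


def adjusted_or(table: CohortTable, subset: AnalysisSubset,
                spec: PredictorSpec) -> list[OddsRatioResult]:
    """Odds ratio(s) adjusted for maternal age, parity and pre-pregnancy BMI.

    When the tested coding is itself a function of BMI or weight, BMI is
    dropped from the adjuster set to keep the design full rank.
    """
    adjusters = adjuster_specs(include_bmi=not spec.uses_bmi)
    design = encode(subset, [spec] + adjusters, table)
    fit = fit_logistic(design)
    return wald_results(fit, design, keep={spec.name})
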