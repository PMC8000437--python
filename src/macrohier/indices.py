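"""Prediction-increment indices: AUC, paired AUC difference, IDI, continuous NRI.

Implements the three indicators used to score the added value of one
predictor over the base risk model, each with a 95 % confidence interval and
a two-sided normal p-value:

* AUC by the Mann-Whitney estimator (ties count one half), with the DeLong
  structural-component variance; paired AUC differences use the DeLong
  covariance of the structural components.
* IDI, the difference between the mean risk change among events and among
  non-events — equivalently the change in discrimination slope — with the
  paired-difference normal standard error.
* Category-free (continuous) NRI, built from the proportions of events and
  non-events whose predicted risk moves up or down when the predictor is
  added; variance by the asymptotic multinomial formula
  Var1 = [u1 + d1 - (u1 - d1)^2] / n1 (and analogously for non-events).

Also provides the minimum-sample-size formula n = Z^2 p (1-p) / d^2 for a
proportion estimated to margin d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IndexResult",
    "NRIDecomposition",
    "auc",
    "auc_difference",
    "idi",
    "nri_continuous",
    "nri_from_proportions",
    "sample_size_min",
]

_Z = float(stats.norm.ppf(0.975))


@dataclass
class IndexResult:
    """One (predictor x index) evaluation."""

    index: str  # AUC | AUC_difference | IDI | NRI
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    predictor: str = ""
    contrast: str = ""


@dataclass
class NRIDecomposition:
    """Event/non-event components of the continuous NRI.

    ``u1``/``d1`` are the proportions of events reclassified up/down;
    ``u0``/``d0`` the same among non-events.  NRI1 = u1 - d1 (events moving
    up is correct), NRI0 = d0 - u0, NRI = NRI1 + NRI0.
    """

    nri1: float
    nri0: float
    d1: float
    u1: float
    d0: float
    u0: float
    n1: int
    n0: int


def _split(scores: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must have equal length")
    ev = scores[outcome == 1]
    ne = scores[outcome == 0]
    if len(ev) == 0 or len(ne) == 0:
        raise ValueError("need at least one event and one non-event")
    return ev, ne


def _delong_components(ev: np.ndarray, ne: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components V10 (events), V01 (non-events)."""
    # psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise
    cmp_ = (ev[:, None] > ne[None, :]).astype(float)
    cmp_ += 0.5 * (ev[:, None] == ne[None, :])
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    return float(v10.mean()), v10, v01


def auc(scores, outcome, predictor: str = "", contrast: str = "") -> IndexResult:
    """Mann-Whitney AUC with DeLong CI; p-value tests AUC = 0.5."""
    ev, ne = _split(np.asarray(scores, dtype=float), np.asarray(outcome))
    a, v10, v01 = _delong_components(ev, ne)
    m, n = len(ev), len(ne)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    lo, hi = max(0.0, a - _Z * se), min(1.0, a + _Z * se)
    z = (a - 0.5) / se if se > 0 else np.inf * np.sign(a - 0.5) if a != 0.5 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return IndexResult("AUC", float(a), lo, hi, p, predictor, contrast)


def auc_difference(p_base, p_ext, outcome, predictor: str = "",
                   contrast: str = "") -> IndexResult:
    """Paired AUC difference AUC(ext) - AUC(base) with DeLong covariance."""
    p_base = np.asarray(p_base, dtype=float)
    p_ext = np.asarray(p_ext, dtype=float)
    outcome = np.asarray(outcome)
    if not (len(p_base) == len(p_ext) == len(outcome)):
        raise ValueError("p_base, p_ext and outcome must have equal length")
    evb, neb = _split(p_base, outcome)
    eve, nee = _split(p_ext, outcome)
    a_b, v10_b, v01_b = _delong_components(evb, neb)
    a_e, v10_e, v01_e = _delong_components(eve, nee)
    m, n = len(evb), len(neb)
    d10 = v10_e - v10_b
    d01 = v01_e - v01_b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(d01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    est = float(a_e - a_b)
    if se > 0:
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if est == 0.0 else 0.0
    return IndexResult("AUC_difference", est, est - _Z * se, est + _Z * se,
                       p, predictor, contrast)


def idi(p_base, p_ext, outcome, predictor: str = "", contrast: str = "") -> IndexResult:
    """Integrated discrimination improvement (change in discrimination slope)."""
    p_base = np.asarray(p_base, dtype=float)
    p_ext = np.asarray(p_ext, dtype=float)
    outcome = np.asarray(outcome)
    diff = p_ext - p_base
    d1 = diff[outcome == 1]
    d0 = diff[outcome == 0]
    if len(d1) == 0 or len(d0) == 0:
        raise ValueError("need at least one event and one non-event")
    est = float(d1.mean() - d0.mean())
    var = (np.var(d1, ddof=1) / len(d1) if len(d1) > 1 else 0.0) + \
          (np.var(d0, ddof=1) / len(d0) if len(d0) > 1 else 0.0)
    se = float(np.sqrt(var))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(est / se)))
    else:
        p = 1.0 if est == 0.0 else 0.0
    return IndexResult("IDI", est, est - _Z * se, est + _Z * se, p,
                       predictor, contrast)


def nri_from_proportions(u1: float, d1: float, u0: float, d0: float,
                         n1: int, n0: int, predictor: str = "",
                         contrast: str = "") -> tuple[IndexResult, NRIDecomposition]:
    """Continuous NRI with CI from up/down proportions and group sizes.

    Accepts the reclassification proportions directly (as fractions), which
    makes printed reclassification tables directly recomputable.
    """
    for nm, v in (("u1", u1), ("d1", d1), ("u0", u0), ("d0", d0)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1]")
    if u1 + d1 > 1.0 + 1e-12 or u0 + d0 > 1.0 + 1e-12:
        raise ValueError("up + down proportions may not exceed 1 within a group")
    nri1 = u1 - d1
    nri0 = d0 - u0
    est = nri1 + nri0
    var1 = (u1 + d1 - nri1 ** 2) / n1
    var0 = (u0 + d0 - nri0 ** 2) / n0
    se = float(np.sqrt(var1 + var0))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(est / se)))
    else:
        p = 1.0 if est == 0.0 else 0.0
    res = IndexResult("NRI", float(est), float(est - _Z * se),
                      float(est + _Z * se), p, predictor, contrast)
    dec = NRIDecomposition(nri1=float(nri1), nri0=float(nri0), d1=float(d1),
                           u1=float(u1), d0=float(d0), u0=float(u0),
                           n1=int(n1), n0=int(n0))
    return res, dec


def nri_continuous(p_base, p_ext, outcome, predictor: str = "",
                   contrast: str = "") -> tuple[IndexResult, NRIDecomposition]:
    """Category-free NRI of adding a predictor to the base model.

    A participant counts as moving up when the extended model assigns a
    strictly higher risk, down when strictly lower; exact ties count as
    neither but stay in the denominators.
    """
    p_base = np.asarray(p_base, dtype=float)
    p_ext = np.asarray(p_ext, dtype=float)
    outcome = np.asarray(outcome)
    if not (len(p_base) == len(p_ext) == len(outcome)):
        raise ValueError("p_base, p_ext and outcome must have equal length")
    ev = outcome == 1
    ne = outcome == 0
    n1, n0 = int(ev.sum()), int(ne.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one event and one non-event")
    up = p_ext > p_base
    down = p_ext < p_base
    u1 = float(up[ev].mean())
    d1 = float(down[ev].mean())
    u0 = float(up[ne].mean())
    d0 = float(down[ne].mean())
    return nri_from_proportions(u1, d1, u0, d0, n1, n0, predictor, contrast)


def sample_size_min(p: float, d: float, alpha: float = 0.05,
                    z: float | None = None) -> int:
    """Minimum n to estimate a proportion p to margin d: n = Z^2 p(1-p) / d^2.

    Z defaults to the exact normal quantile at alpha/2 and may be overridden
    (some sources round it, which changes the truncated result).  The result
    is truncated to an integer.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if d <= 0:
        raise ValueError("margin d must be positive")
    if z is None:
        z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return int(z * z * p * (1.0 - p) / (d * d))
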