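"""Method-of-moments estimators of the between-study variance.

All members of this family equate a quadratic heterogeneity statistic to its
expectation under the random-effects model and solve for tau^2.  The
generalised method of moments (GMM) estimator with weights a_i,

    tau^2 = max(0, [Q_a - (sum a v - sum a^2 v / sum a)]
                   / [sum a - sum a^2 / sum a]),

contains DL (a_i = 1/v_i), HO (a_i constant), and the two-step DL2/HO2
variants (a_i = RE weights at a first-step estimate) as special cases.  The
Paule–Mandel estimator profiles Q_gen(tau^2) to its expectation k - 1.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .data_model import (
    ConvergenceError,
    DegenerateSchemeError,
    EstimatorOptions,
    MetaDataset,
    Tau2Estimate,
    make_estimate,
)
from .pooling import WeightingScheme, cochran_q, generalized_q, q_gen, weight_sums

__all__ = [
    "estimate_gmm",
    "estimate_dl",
    "estimate_dlp",
    "estimate_dl2",
    "estimate_ho",
    "estimate_ho2",
    "estimate_pm",
    "estimate_hm",
    "estimate_hs",
]

_DEFAULT = EstimatorOptions()


def _gmm_untruncated(data: MetaDataset, a: np.ndarray) -> float:
    sa = a.sum()
    denom = sa - (a**2).sum() / sa
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateSchemeError("degenerate scheme: weight mass on a single study")
    mu = np.dot(a, data.y) / sa
    qa = np.dot(a, (data.y - mu) ** 2)
    bias_term = np.dot(a, data.v) - np.dot(a**2, data.v) / sa
    return float((qa - bias_term) / denom)


def estimate_gmm(data: MetaDataset, scheme: WeightingScheme,
                 method: str = "GMM") -> Tau2Estimate:
    """Generalised method-of-moments estimator for an arbitrary scheme."""
    a = scheme.weights(data)
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise DegenerateSchemeError("weights must be positive and finite")
    return make_estimate(method, _gmm_untruncated(data, a))


def estimate_dl(data: MetaDataset) -> Tau2Estimate:
    """DerSimonian–Laird: GMM with fixed-effect weights 1/v_i."""
    q = cochran_q(data)
    s = weight_sums(data)
    untrunc = (q - (data.k - 1)) / (s.s1 - s.s2 / s.s1)
    return make_estimate("DL", untrunc)


def estimate_dlp(data: MetaDataset, opts: EstimatorOptions = _DEFAULT) -> Tau2Estimate:
    """Positive DL: returns DL when positive, else the constant c (0.01)."""
    dl = estimate_dl(data)
    if dl.tau2 > 0:
        return Tau2Estimate("DLp", dl.tau2, dl.tau2_untruncated, False)
    # substituted constant; untruncated value of DL retained for bias studies
    return Tau2Estimate("DLp", opts.c, dl.tau2_untruncated, True)


def estimate_dl2(data: MetaDataset) -> Tau2Estimate:
    """Two-step DL: GMM with RE weights at the first-step DL estimate."""
    step1 = estimate_dl(data).tau2
    scheme = WeightingScheme.random_effects(step1)
    return estimate_gmm(data, scheme, method="DL2")


def estimate_ho(data: MetaDataset) -> Tau2Estimate:
    """Hedges–Olkin: unweighted sample variance minus mean within-variance."""
    ybar = data.y.mean()
    untrunc = ((data.y - ybar) ** 2).sum() / (data.k - 1) - data.v.mean()
    return make_estimate("HO", float(untrunc))


def estimate_ho2(data: MetaDataset) -> Tau2Estimate:
    """Two-step HO: GMM with RE weights at the first-step HO estimate."""
    step1 = estimate_ho(data).tau2
    scheme = WeightingScheme.random_effects(step1)
    return estimate_gmm(data, scheme, method="HO2")


def estimate_pm(data: MetaDataset, opts: EstimatorOptions = _DEFAULT) -> Tau2Estimate:
    """Paule–Mandel: the root of Q_gen(tau^2) = k - 1.

    Q_gen is monotone decreasing, so the root is unique; it is bracketed by
    doubling the upper end from max(v_i) and located with Brent's method.
    When Q_gen(0) <= k - 1 the estimate is zero.
    """
    target = data.k - 1
    f0 = q_gen(data, 0.0) - target
    if f0 <= 0:
        # Q_gen(0) <= k - 1: the defining equation has no positive root and
        # the estimate is 0 by definition (no truncation involved).
        return Tau2Estimate("PM", 0.0, 0.0, False, iterations=0, converged=True)
    hi = float(data.v.max())
    it = 0
    while q_gen(data, hi) - target > 0:
        hi *= 2.0
        it += 1
        if it > opts.max_iter:
            raise ConvergenceError(
                "PM bracket expansion exceeded max_iter", trace=[0.0, hi]
            )
    root, res = brentq(lambda t: q_gen(data, t) - target, 0.0, hi,
                       xtol=opts.tol, maxiter=200, full_output=True)
    if not res.converged:
        raise ConvergenceError("PM root search did not converge",
                               trace=[0.0, hi, root])
    return Tau2Estimate("PM", float(root), float(root), False,
                        iterations=res.iterations + it, converged=True)


def estimate_hm(data: MetaDataset) -> Tau2Estimate:
    """Hartung–Makambi: DL's quadratic form damped by Q/(2(k-1)+Q).

    Positive whenever Q > 0; at Q = 0 (perfectly homogeneous data) the
    formula itself vanishes and 0 is returned — a boundary convention, since
    no truncation is ever applied.
    """
    q = cochran_q(data)
    s = weight_sums(data)
    val = q**2 / ((2 * (data.k - 1) + q) * (s.s1 - s.s2 / s.s1))
    return Tau2Estimate("HM", float(val), float(val), False)


def estimate_hs(data: MetaDataset) -> Tau2Estimate:
    """Hunter–Schmidt: max(0, (Q - k) / S1); negatively biased."""
    q = cochran_q(data)
    s = weight_sums(data)
    return make_estimate("HS", (q - data.k) / s.s1)
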