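"""Confidence intervals for the between-study variance.

Seven families are implemented, each self-verifying in the sense that the
returned bounds satisfy their defining equations to root-finder tolerance:

* PL — profile-likelihood inversion of the chi-square(1) likelihood-ratio
  cutoff.
* Wt — Wald-type intervals from the ML/REML Fisher-information variances.
* BT — gamma moment-matching approximation of Cochran's Q, tail equations
  inverted in tau^2.
* BJ — exact chi-squared-mixture cdf of Q inverted in tau^2 (DL or HM form).
* Jackson — the same inversion for the generalised Q_a with arbitrary
  weights (default: reciprocal within-study standard errors), exact under
  the random-effects model.
* QP — Q-profile: Q_gen(tau^2) inverted against chi-square(k-1) quantiles,
  also exact under the model.
* SJ — chi-square(k-1) scaling of the Sidik–Jonkman estimate (never
  contains zero).
* Bootstrap — parametric or nonparametric percentile intervals for any base
  estimator.

Failed inversions (null sets) are reported as [0, 0] with degenerate=True.
A warning is emitted whenever an interval excludes its paired point
estimate, which the Q-profile/Paule–Mandel pairing structurally avoids.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Optional

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .auxiliary_estimators import estimate_sj
from .data_model import (
    ConvergenceError,
    EstimatorOptions,
    MetaDataset,
    Tau2Interval,
)
from .likelihood_estimators import (
    asymptotic_variance,
    estimate_ml,
    estimate_reml,
    profile_log_likelihood,
)
from .moment_estimators import estimate_dl, estimate_hm, estimate_pm
from .pooling import WeightingScheme, cochran_q, generalized_q, pooled_effect, q_gen
from .qdist import gamma_moments, mixture_cdf, mixture_coefficients

__all__ = [
    "IntervalPointMismatchWarning",
    "ci_pl",
    "ci_wald",
    "ci_bt",
    "ci_bj",
    "ci_jackson",
    "ci_qp",
    "ci_sj",
    "ci_bootstrap",
    "compatibility",
    "compatibility_matrix",
]

logger = logging.getLogger(__name__)

_DEFAULT = EstimatorOptions()

# Root searches in tau^2 expand the bracket by doubling from max(v_i) up to
# this multiple of max(v_i); hitting the cap is an explicit error.
_BRACKET_CAP = 1e4


class IntervalPointMismatchWarning(UserWarning):
    """The interval excludes the point estimate it is paired with."""


def _expand_bracket(f: Callable[[float], float], data: MetaDataset,
                    what: str) -> float:
    """Find hi with f(hi) < 0 by doubling from max(v_i); f(0) must be > 0."""
    hi = float(data.v.max())
    cap = _BRACKET_CAP * hi
    while f(hi) > 0:
        hi *= 2.0
        if hi > cap:
            raise ConvergenceError(
                f"{what}: no sign change in tau^2 below bracket cap {cap:.3g}"
            )
    return hi


def _solve(f: Callable[[float], float], data: MetaDataset, what: str,
           xtol: float = 1e-10) -> float:
    """Root of a decreasing function of tau^2 with f(0) > 0."""
    hi = _expand_bracket(f, data, what)
    return float(brentq(f, 0.0, hi, xtol=xtol, maxiter=200))


def _null_set(method: str, level: float, point_method: str,
              point: float) -> Tau2Interval:
    logger.info(
        "%s interval at level %.3g is the null set [0, 0]: "
        "the data appear to be highly homogeneous", method, level)
    return Tau2Interval(method=method, level=level, lower=0.0, upper=0.0,
                        degenerate=True, point_method=point_method,
                        point_estimate=point)


def _check_point(iv: Tau2Interval) -> Tau2Interval:
    if iv.point_estimate is not None and not iv.degenerate \
            and not iv.contains(iv.point_estimate):
        warnings.warn(
            f"{iv.method} interval [{iv.lower:.4g}, {iv.upper:.4g}] excludes "
            f"its paired {iv.point_method} estimate {iv.point_estimate:.4g}",
            IntervalPointMismatchWarning,
        )
    return iv


# --- profile likelihood --------------------------------------------------

def ci_pl(data: MetaDataset, level: float = 0.95,
          opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Profile-likelihood interval: tau^2 with lnL within chi2(1)/2 of max."""
    ml = estimate_ml(data, opts)
    cutoff = profile_log_likelihood(data, ml.tau2) - 0.5 * stats.chi2.ppf(level, 1)

    def g(t):      # positive inside the interval
        return profile_log_likelihood(data, t) - cutoff

    if g(0.0) >= 0:
        lower = 0.0
    else:
        lower = float(brentq(g, 0.0, ml.tau2, xtol=1e-10, maxiter=200))
    # the profile likelihood is unimodal: bracket the upper root above the MLE
    hi = max(float(data.v.max()), 2 * ml.tau2 + 1e-12)
    cap = _BRACKET_CAP * hi
    while g(hi) > 0:
        hi *= 2.0
        if hi > cap:
            raise ConvergenceError(
                f"PL upper bound: no crossing below bracket cap {cap:.3g}")
    upper = float(brentq(g, ml.tau2, hi, xtol=1e-10, maxiter=200))
    return _check_point(Tau2Interval(
        method="PL", level=level, lower=lower, upper=max(upper, lower),
        point_method="ML", point_estimate=ml.tau2))


# --- Wald ----------------------------------------------------------------

def ci_wald(data: MetaDataset, level: float = 0.95, kind: str = "ML",
            opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Wald-type interval tau^2 +/- z * sqrt(Var), lower truncated at 0."""
    if kind == "ML":
        est = estimate_ml(data, opts)
    elif kind == "REML":
        est = estimate_reml(data, opts)
    else:
        raise ValueError("kind must be 'ML' or 'REML'")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(asymptotic_variance(data, est.tau2, kind).var_tau2)
    return _check_point(Tau2Interval(
        method=f"Wt_{kind}", level=level,
        lower=max(0.0, est.tau2 - half), upper=est.tau2 + half,
        point_method=kind, point_estimate=est.tau2))


# --- Biggerstaff–Tweedie -------------------------------------------------

def ci_bt(data: MetaDataset, level: float = 0.95) -> Tau2Interval:
    """Gamma-approximation interval: tail equations of Q solved in tau^2."""
    q = cochran_q(data)
    alpha = 1.0 - level
    point = estimate_dl(data)

    def cdf_at_q(t):
        g = gamma_moments(data, t)
        return stats.gamma.cdf(q / g.lam, a=g.r)

    if cdf_at_q(0.0) < alpha / 2:
        return _null_set("BT", level, "DL", point.tau2)
    # lower bound: upper-tail probability alpha/2, i.e. cdf = 1 - alpha/2
    if cdf_at_q(0.0) <= 1.0 - alpha / 2:
        lower = 0.0
    else:
        lower = _solve(lambda t: cdf_at_q(t) - (1.0 - alpha / 2), data,
                       "BT lower bound")
    upper = _solve(lambda t: cdf_at_q(t) - alpha / 2, data, "BT upper bound")
    return _check_point(Tau2Interval(
        method="BT", level=level, lower=lower, upper=max(upper, lower),
        point_method="DL", point_estimate=point.tau2))


# --- chi-squared-mixture inversions (BJ, Jackson) ------------------------

def _mixture_ci(data: MetaDataset, statistic_value: float, level: float,
                scheme: WeightingScheme, method: str, point_method: str,
                point: float,
                transform: Optional[Callable] = None) -> Tau2Interval:
    """Invert F(statistic; tau^2) = alpha/2 and 1 - alpha/2 in tau^2.

    ``transform(x, tau2) -> probability`` overrides the plain mixture cdf
    (used for the HM functional of Q).  F is decreasing in tau^2.
    """
    alpha = 1.0 - level

    def cdf(t):
        if transform is not None:
            return transform(statistic_value, t)
        return mixture_cdf(mixture_coefficients(data, t, scheme),
                           statistic_value)

    f0 = cdf(0.0)
    if f0 < alpha / 2:
        return _null_set(method, level, point_method, point)
    if f0 <= 1.0 - alpha / 2:        # 1 - F(x; 0) > alpha/2
        lower = 0.0
    else:
        lower = _solve(lambda t: cdf(t) - (1.0 - alpha / 2), data,
                       f"{method} lower bound")
    upper = _solve(lambda t: cdf(t) - alpha / 2, data,
                   f"{method} upper bound")
    return _check_point(Tau2Interval(
        method=method, level=level, lower=lower, upper=max(upper, lower),
        point_method=point_method, point_estimate=point))


def ci_bj(data: MetaDataset, level: float = 0.95,
          statistic: str = "DL") -> Tau2Interval:
    """Biggerstaff–Jackson interval from the exact distribution of Q.

    statistic='DL' inverts the cdf of Q itself (the untruncated DL estimate
    is a linear function of Q, so the two are equivalent); statistic='HM'
    inverts the distribution of the Hartung–Makambi functional of Q.
    """
    q_obs = cochran_q(data)
    scheme = WeightingScheme.fixed_effect()
    if statistic == "DL":
        return _mixture_ci(data, q_obs, level, scheme, "BJ_DL", "DL",
                           estimate_dl(data).tau2)
    if statistic != "HM":
        raise ValueError("statistic must be 'DL' or 'HM'")
    w = 1.0 / data.v
    s = w.sum() - (w**2).sum() / w.sum()
    hm = estimate_hm(data)

    def hm_cdf(x, t):
        # P(tau2_HM <= x) = F_Q(sx/2 + sqrt(2(k-1)sx + (sx/2)^2))
        #                 - F_Q(sx/2 - sqrt(...)); the lower root is
        # negative for x > 0 so the second term vanishes.
        sx = s * x
        root = np.sqrt(2 * (data.k - 1) * sx + (sx / 2) ** 2)
        mix = mixture_coefficients(data, t, scheme)
        hi_arg = sx / 2 + root
        lo_arg = sx / 2 - root
        p = mixture_cdf(mix, hi_arg)
        if lo_arg > 0:
            p -= mixture_cdf(mix, lo_arg)
        return p

    return _mixture_ci(data, hm.tau2, level, scheme, "BJ_HM", "HM", hm.tau2,
                       transform=hm_cdf)


def ci_jackson(data: MetaDataset, level: float = 0.95,
               scheme: Optional[WeightingScheme] = None) -> Tau2Interval:
    """Jackson generalised-Q interval; default weights 1/sqrt(v_i)."""
    if scheme is None:
        scheme = WeightingScheme.reciprocal_se()
    qa_obs = generalized_q(data, scheme)
    return _mixture_ci(data, qa_obs, level, scheme, "Jackson", "DL",
                       estimate_dl(data).tau2)


# --- Q-profile -----------------------------------------------------------

def ci_qp(data: MetaDataset, level: float = 0.95,
          opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Q-profile interval: Q_gen inverted against chi-square(k-1) quantiles."""
    alpha = 1.0 - level
    chi_lo = stats.chi2.ppf(alpha / 2, data.k - 1)
    chi_hi = stats.chi2.ppf(1.0 - alpha / 2, data.k - 1)
    q0 = q_gen(data, 0.0)
    point = estimate_pm(data, opts)
    if q0 < chi_lo:        # upper bound would fall below zero
        return _null_set("QP", level, "PM", point.tau2)
    lower = 0.0 if q0 < chi_hi else _solve(
        lambda t: q_gen(data, t) - chi_hi, data, "QP lower bound")
    upper = _solve(lambda t: q_gen(data, t) - chi_lo, data, "QP upper bound")
    return _check_point(Tau2Interval(
        method="QP", level=level, lower=lower, upper=max(upper, lower),
        point_method="PM", point_estimate=point.tau2))


# --- Sidik–Jonkman -------------------------------------------------------

def ci_sj(data: MetaDataset, level: float = 0.95,
          opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Chi-square scaling of the SJ estimate; bounds are strictly positive."""
    alpha = 1.0 - level
    est = estimate_sj(data, opts)
    df = data.k - 1
    return _check_point(Tau2Interval(
        method="SJ", level=level,
        lower=df * est.tau2 / stats.chi2.ppf(1.0 - alpha / 2, df),
        upper=df * est.tau2 / stats.chi2.ppf(alpha / 2, df),
        point_method="SJ", point_estimate=est.tau2))


# --- bootstrap -----------------------------------------------------------

def ci_bootstrap(data: MetaDataset, level: float = 0.95,
                 mode: str = "nonparametric", base: str = "DL",
                 opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Percentile bootstrap interval for any base estimator.

    Parametric mode redraws y_i ~ N(mu_RE(tau^2), tau^2 + v_i) at the base
    estimate; nonparametric mode resamples (y_i, v_i) pairs with
    replacement.  Deterministic given opts.seed.
    """
    from .registry import get_estimator

    if mode not in ("parametric", "nonparametric"):
        raise ValueError("mode must be 'parametric' or 'nonparametric'")
    fn = get_estimator(base)
    point = fn(data, opts).tau2
    rng = np.random.default_rng(opts.seed)
    values = []
    failures = 0
    for _ in range(opts.B):
        try:
            if mode == "parametric":
                mu = pooled_effect(data, point).mu
                y_star = rng.normal(mu, np.sqrt(point + data.v))
                boot = MetaDataset.from_arrays(y_star, data.v)
            else:
                idx = rng.integers(0, data.k, size=data.k)
                boot = data.resample(idx)
            values.append(fn(boot, opts).tau2)
        except Exception:
            failures += 1
    if failures > 0.5 * opts.B or not values:
        raise ConvergenceError(
            f"bootstrap: {failures}/{opts.B} replicates failed")
    alpha = 1.0 - level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    method = "BootPar" if mode == "parametric" else "BootNonpar"
    return _check_point(Tau2Interval(
        method=method, level=level, lower=float(lo), upper=float(hi),
        degenerate=False, point_method=base, point_estimate=point))


# --- compatibility matrix ------------------------------------------------

# Estimator tag -> cell per interval column group, following the published
# pairing recommendations: 'natural' (checkmark), 'in_principle'
# (parenthesised checkmark), 'incompatible' (dash).
_COLUMNS = {"PL": "PL", "Wt_ML": "Wt", "Wt_REML": "Wt", "BT": "BTJ",
            "BJ_DL": "BTJ", "BJ_HM": "BTJ", "Jackson": "BTJ", "QP": "QP",
            "SJ": "SJ", "BootPar": "Boot", "BootNonpar": "Boot",
            "Credible": "Cred"}

_N, _P, _X = "natural", "in_principle", "incompatible"

_ROWS = {
    #          PL   Wt   BTJ  QP   SJ   Boot Cred
    "DL":    (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "DLp":   (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "DL2":   (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "HO":    (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "HO2":   (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "PM":    (_X,  _N,  _P,  _N,  _X,  _N,  _X),
    "HM":    (_X,  _N,  _N,  _P,  _X,  _N,  _X),
    "HS":    (_X,  _N,  _P,  _P,  _X,  _N,  _X),
    "ML":    (_N,  _N,  _P,  _P,  _X,  _N,  _X),
    "REML":  (_N,  _N,  _P,  _P,  _X,  _N,  _X),
    "AREML": (_N,  _N,  _P,  _P,  _X,  _N,  _X),
    "SJ":    (_X,  _N,  _P,  _P,  _N,  _N,  _X),
    "RB0":   (_X,  _N,  _P,  _P,  _X,  _N,  _N),
    "RBp":   (_X,  _N,  _P,  _P,  _X,  _N,  _X),
    "FB":    (_X,  _X,  _X,  _X,  _X,  _X,  _N),
    "BM":    (_X,  _N,  _P,  _P,  _X,  _N,  _X),
    "DLb":   (_X,  _N,  _P,  _P,  _X,  _N,  _X),
}
_COL_ORDER = ("PL", "Wt", "BTJ", "QP", "SJ", "Boot", "Cred")


def compatibility(estimator: str, interval: str) -> str:
    """Pairing class for an (estimator, interval) combination."""
    if estimator not in _ROWS:
        raise KeyError(f"unknown estimator tag {estimator!r}")
    if interval not in _COLUMNS:
        raise KeyError(f"unknown interval tag {interval!r}")
    return _ROWS[estimator][_COL_ORDER.index(_COLUMNS[interval])]


def compatibility_matrix() -> dict:
    """Full (estimator, interval) -> class mapping."""
    return {(e, i): compatibility(e, i) for e in _ROWS for i in _COLUMNS}
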