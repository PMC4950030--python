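"""Dispatch from estimator / interval tags to the implementing callables."""

from __future__ import annotations

from typing import Callable, Optional

from . import auxiliary_estimators as aux
from . import bayes_fb, likelihood_estimators as lik, moment_estimators as mom
from .data_model import (
    ESTIMATOR_TAGS,
    EstimatorOptions,
    MetaDataset,
    Tau2Estimate,
    Tau2Interval,
)

__all__ = ["get_estimator", "estimate", "get_interval", "interval"]

_DEFAULT = EstimatorOptions()


def _rb0(data, opts):
    return aux.estimate_rb(data, 0.0 if opts.tau2_prior is None else opts.tau2_prior)


_ESTIMATORS: dict[str, Callable[[MetaDataset, EstimatorOptions], Tau2Estimate]] = {
    "DL": lambda d, o: mom.estimate_dl(d),
    "DLp": mom.estimate_dlp,
    "DL2": lambda d, o: mom.estimate_dl2(d),
    "DLb": aux.estimate_dlb,
    "HO": lambda d, o: mom.estimate_ho(d),
    "HO2": lambda d, o: mom.estimate_ho2(d),
    "PM": mom.estimate_pm,
    "HM": lambda d, o: mom.estimate_hm(d),
    "HS": lambda d, o: mom.estimate_hs(d),
    "ML": lik.estimate_ml,
    "REML": lik.estimate_reml,
    "AREML": lik.estimate_areml,
    "SJ": aux.estimate_sj,
    "RB0": _rb0,
    "RBp": lambda d, o: aux.estimate_rbp(d),
    "BM": aux.estimate_bm,
    "FB": lambda d, o: bayes_fb.fb_estimate(d),
}

assert set(_ESTIMATORS) == set(ESTIMATOR_TAGS)


def get_estimator(tag: str) -> Callable[[MetaDataset, EstimatorOptions], Tau2Estimate]:
    try:
        return _ESTIMATORS[tag]
    except KeyError:
        raise KeyError(
            f"unknown estimator tag {tag!r}; valid tags: {', '.join(ESTIMATOR_TAGS)}"
        )


def estimate(tag: str, data: MetaDataset,
             opts: EstimatorOptions = _DEFAULT) -> Tau2Estimate:
    """Compute the tau^2 estimate for a method tag."""
    return get_estimator(tag)(data, opts)


def interval(tag: str, data: MetaDataset, level: float = 0.95,
             opts: EstimatorOptions = _DEFAULT) -> Tau2Interval:
    """Compute the tau^2 interval for an interval-method tag."""
    from . import intervals as iv

    dispatch: dict[str, Callable[[], Tau2Interval]] = {
        "PL": lambda: iv.ci_pl(data, level, opts),
        "Wt_ML": lambda: iv.ci_wald(data, level, "ML", opts),
        "Wt_REML": lambda: iv.ci_wald(data, level, "REML", opts),
        "BT": lambda: iv.ci_bt(data, level),
        "BJ_DL": lambda: iv.ci_bj(data, level, "DL"),
        "BJ_HM": lambda: iv.ci_bj(data, level, "HM"),
        "Jackson": lambda: iv.ci_jackson(data, level),
        "QP": lambda: iv.ci_qp(data, level, opts),
        "SJ": lambda: iv.ci_sj(data, level, opts),
        "BootPar": lambda: iv.ci_bootstrap(data, level, "parametric", "DL", opts),
        "BootNonpar": lambda: iv.ci_bootstrap(data, level, "nonparametric", "DL", opts),
        "Credible": lambda: bayes_fb.fb_credible_interval(data, level=level),
    }
    try:
        fn = dispatch[tag]
    except KeyError:
        raise KeyError(f"unknown interval tag {tag!r}; valid tags: "
                       f"{', '.join(dispatch)}")
    return fn()


def get_interval(tag: str):
    return lambda data, level=0.95, opts=_DEFAULT: interval(tag, data, level, opts)
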