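"""Domain types and validation for meta-analytic input data.

The universal input is a set of k independent studies, each contributing an
effect estimate ``y_i`` on some effect scale (log odds ratio, log hazard
ratio, mean difference, ...) together with its within-study sampling variance
``v_i``, conventionally treated as known.  Per-study total sample sizes
``n_i`` are optional and only required by the Rukhin Bayes estimator family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "InsufficientStudiesError",
    "MissingSampleSizesError",
    "ConvergenceError",
    "DegenerateSchemeError",
    "StudyRecord",
    "MetaDataset",
    "Tau2Estimate",
    "Tau2Interval",
    "EstimatorOptions",
    "POSITIVE_METHODS",
    "ESTIMATOR_TAGS",
    "INTERVAL_TAGS",
    "validate_dataset",
    "fixture",
]


class ValidationError(ValueError):
    """Raised when input data violate a dataset invariant."""


class InsufficientStudiesError(ValidationError):
    """Raised when fewer than two studies are supplied."""


class MissingSampleSizesError(ValidationError):
    """Raised when an estimator requiring per-study sample sizes gets none."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative estimator fails to converge; carries a trace."""

    def __init__(self, message: str, trace: Optional[Sequence[float]] = None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class DegenerateSchemeError(ValueError):
    """Raised when a weighting scheme concentrates all mass on one study."""


# Estimator tags, in the order they are conventionally tabulated.
ESTIMATOR_TAGS = (
    "DL", "DLp", "DL2", "DLb", "HO", "HO2", "PM", "HM", "HS",
    "ML", "REML", "AREML", "SJ", "RB0", "RBp", "BM", "FB",
)

# Methods that by construction return a strictly positive estimate.  HM is
# classified positive but its closed form vanishes at Q = 0 (homogeneous
# data); that boundary convention is documented in moment_estimators.
POSITIVE_METHODS = frozenset({"DLp", "HM", "SJ", "RBp", "BM"})

INTERVAL_TAGS = (
    "PL", "Wt_ML", "Wt_REML", "BT", "BJ_DL", "BJ_HM", "Jackson",
    "QP", "SJ", "BootPar", "BootNonpar", "Credible",
)


@dataclass(frozen=True)
class StudyRecord:
    """One study's summary data: effect estimate, variance, optional size."""

    label: str
    y: float
    v: float
    n: Optional[int] = None

    def __post_init__(self):
        if not math.isfinite(self.y):
            raise ValidationError(f"study {self.label!r}: non-finite effect estimate")
        if not math.isfinite(self.v) or self.v <= 0:
            raise ValidationError(f"study {self.label!r}: non-positive variance")
        if self.n is not None:
            if int(self.n) != self.n or self.n < 2:
                raise ValidationError(
                    f"study {self.label!r}: sample size must be an integer >= 2"
                )


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of studies; the input to every estimator.

    Input order is preserved (all statistics are permutation invariant, which
    is tested rather than assumed).  Arrays are exposed as read-only views.
    """

    studies: tuple[StudyRecord, ...]

    def __post_init__(self):
        if len(self.studies) < 2:
            raise InsufficientStudiesError(
                f"insufficient studies: k={len(self.studies)} < 2"
            )
        labels = [s.label for s in self.studies]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate study labels: {dup}")

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.studies)

    @property
    def y(self) -> np.ndarray:
        arr = np.array([s.y for s in self.studies], dtype=float)
        arr.flags.writeable = False
        return arr

    @property
    def v(self) -> np.ndarray:
        arr = np.array([s.v for s in self.studies], dtype=float)
        arr.flags.writeable = False
        return arr

    @property
    def has_n(self) -> bool:
        return all(s.n is not None for s in self.studies)

    @property
    def n(self) -> Optional[np.ndarray]:
        if not self.has_n:
            return None
        arr = np.array([s.n for s in self.studies], dtype=float)
        arr.flags.writeable = False
        return arr

    def require_n(self, method: str = "this estimator") -> np.ndarray:
        n = self.n
        if n is None:
            raise MissingSampleSizesError(
                f"sample sizes required: {method} needs n_i for every study"
            )
        return n

    @classmethod
    def from_arrays(
        cls,
        y: Iterable[float],
        v: Optional[Iterable[float]] = None,
        *,
        se: Optional[Iterable[float]] = None,
        n: Optional[Iterable[int]] = None,
        labels: Optional[Iterable[str]] = None,
    ) -> "MetaDataset":
        """Build a dataset from parallel arrays.

        Exactly one of ``v`` (variances) or ``se`` (standard errors) must be
        given; standard errors are squared here, at ingestion, and never
        downstream.
        """
        y = list(map(float, y))
        if (v is None) == (se is None):
            raise ValidationError("supply exactly one of v (variances) or se")
        if se is not None:
            v = [float(s) ** 2 for s in se]
        else:
            v = list(map(float, v))
        if labels is None:
            labels = [f"study_{i + 1}" for i in range(len(y))]
        else:
            labels = [str(l) for l in labels]
        ns: list[Optional[int]] = [None] * len(y) if n is None else [int(x) for x in n]
        if not (len(y) == len(v) == len(labels) == len(ns)):
            raise ValidationError("y, v/se, labels and n must have equal length")
        return cls(tuple(StudyRecord(l, yy, vv, nn) for l, yy, vv, nn in zip(labels, y, v, ns)))

    def resample(self, indices: Sequence[int]) -> "MetaDataset":
        """Dataset made of the studies at ``indices`` (with replacement).

        Labels are suffixed with position to keep them unique.
        """
        studies = tuple(
            replace(self.studies[i], label=f"{self.studies[i].label}#{pos}")
            for pos, i in enumerate(indices)
        )
        return MetaDataset(studies)

    def to_records(self) -> list[tuple]:
        """Serialise to plain tuples; inverse of :func:`validate_dataset`."""
        return [
            (s.label, s.y, s.v) if s.n is None else (s.label, s.y, s.v, s.n)
            for s in self.studies
        ]


@dataclass(frozen=True)
class Tau2Estimate:
    """A point estimate of the between-study variance tau^2.

    ``tau2_untruncated`` is the signed value before the max(0, .) truncation;
    it is always retained so that bias studies can work with the untruncated
    estimator.  ``truncated`` is True iff the untruncated value was negative.
    """

    method: str
    tau2: float
    tau2_untruncated: float
    truncated: bool = False
    iterations: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


def make_estimate(method: str, untruncated: float, iterations: int = 0,
                  converged: bool = True) -> Tau2Estimate:
    """Apply the truncation convention once, at the end (strict < 0 test)."""
    truncated = untruncated < 0
    return Tau2Estimate(
        method=method,
        tau2=max(0.0, float(untruncated)),
        tau2_untruncated=float(untruncated),
        truncated=truncated,
        iterations=iterations,
        converged=converged,
    )


@dataclass(frozen=True)
class Tau2Interval:
    """A confidence or credible interval for tau^2.

    A failed inversion (null set) is reported as [0, 0] with
    ``degenerate=True``, interpreted as 'the data appear to be highly
    homogeneous' / 'the interval estimation fails'.
    """

    method: str
    level: float
    lower: float
    upper: float
    degenerate: bool = False
    point_method: Optional[str] = None
    point_estimate: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.level < 1):
            raise ValueError("level must lie in (0, 1)")
        if not (0 <= self.lower <= self.upper):
            raise ValueError("interval must satisfy 0 <= lower <= upper")
        if self.degenerate and not (self.lower == self.upper == 0.0):
            raise ValueError("degenerate interval must be [0, 0]")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class EstimatorOptions:
    """Shared tuning knobs for the estimators.

    c
        Positive constant returned by DLp when DL truncates to zero
        (effect-variance units; default 0.01).
    B
        Bootstrap replicate count for DLb / bootstrap intervals.
    tau2_prior
        Prior mean of tau^2 for the Rukhin Bayes family.
    seed
        Seed for every stochastic routine (bootstrap).
    tol, max_iter
        Convergence tolerance on tau^2 and iteration cap for the iterative
        estimators.
    sj_variant
        'original' uses tau0^2 = sum (y - ybar)^2 / k; 'improved' uses the
        HO estimate with the 0.01 substitution when HO is zero.
    reml_mu
        'self_consistent' recomputes the weighted mean with current REML
        weights at each iteration; 'ml' freezes it at the ML-weighted mean.
    """

    c: float = 0.01
    B: int = 1000
    tau2_prior: Optional[float] = None
    seed: int = 0
    tol: float = 1e-10
    max_iter: int = 100
    sj_variant: str = "original"
    reml_mu: str = "self_consistent"

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.sj_variant not in ("original", "improved"):
            raise ValueError("sj_variant must be 'original' or 'improved'")
        if self.reml_mu not in ("self_consistent", "ml"):
            raise ValueError("reml_mu must be 'self_consistent' or 'ml'")


def validate_dataset(raw: Sequence[Sequence]) -> MetaDataset:
    """Validate a sequence of ``(label, y, v[, n])`` tuples into a dataset."""
    if len(raw) == 0:
        raise ValidationError("empty input: no studies supplied")
    studies = []
    for row in raw:
        if len(row) == 3:
            label, y, v = row
            n = None
        elif len(row) == 4:
            label, y, v, n = row
        else:
            raise ValidationError(f"row {row!r}: expected (label, y, v[, n])")
        studies.append(StudyRecord(str(label), float(y), float(v),
                                   None if n is None else int(n)))
    if len(studies) < 2:
        raise InsufficientStudiesError(
            f"insufficient studies: k={len(studies)} < 2"
        )
    return MetaDataset(tuple(studies))


_FIXTURES = {
    # homogeneous: identical effects, equal variances
    "F0": dict(y=(0.5, 0.5, 0.5), v=(0.1, 0.1, 0.1), n=None),
    # heterogeneous, equal variances
    "F1": dict(y=(0.0, 0.5, 1.0), v=(0.1, 0.1, 0.1), n=None),
    # heterogeneous, unequal variances, sample sizes attached
    "F2": dict(y=(0.0, 0.5, 1.0), v=(0.05, 0.1, 0.2), n=(20, 40, 60)),
}


def fixture(name: str) -> MetaDataset:
    """Canonical deterministic three-study datasets used across the tests."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; valid: {sorted(_FIXTURES)}")
    return MetaDataset.from_arrays(spec["y"], spec["v"], n=spec["n"],
                                   labels=[f"{name}_{c}" for c in "ABC"])
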