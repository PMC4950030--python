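"""Fixed-effect and random-effects pooling, Q statistics, and I².

Under the fixed-effect (FE) model every study shares one true effect and
weights are w_i = 1/v_i; under the random-effects (RE) model true effects are
N(mu, tau^2) and weights are w_i = 1/(v_i + tau^2).  In both cases the pooled
effect is the inverse-variance weighted mean with variance 1 / sum(w).

Three quadratic heterogeneity statistics live here:

* Cochran's Q: FE-weighted squared deviations about the FE pooled mean.
* The generalised Q_a: the same with an arbitrary positive weighting scheme.
* Q_gen(tau^2): Q_a with RE weights, the pooled mean re-profiled at each
  candidate tau^2 — a pivotal quantity that is chi-square(k-1) under the RE
  model and strictly decreasing in tau^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import DegenerateSchemeError, MetaDataset

__all__ = [
    "PooledEffect",
    "WeightingScheme",
    "WeightSums",
    "pooled_effect",
    "cochran_q",
    "generalized_q",
    "q_gen",
    "weight_sums",
    "i_squared",
]


@dataclass(frozen=True)
class PooledEffect:
    model: str            # "FE" or "RE"
    tau2_used: float
    mu: float
    var_mu: float
    weights: np.ndarray

    @property
    def se_mu(self) -> float:
        return float(np.sqrt(self.var_mu))


@dataclass(frozen=True)
class WeightingScheme:
    """Per-study weights a_i, either explicit or the family 1/(v_i + x)^p.

    The parametric family covers the common special cases: x=0, p=1 gives
    fixed-effect weights 1/v_i; x=tau^2, p=1 gives random-effects weights;
    x=0, p=1/2 gives reciprocal standard errors (the Jackson default).
    """

    a: Optional[tuple[float, ...]] = None
    x: float = 0.0
    p: float = 1.0

    def __post_init__(self):
        if self.a is not None:
            arr = np.asarray(self.a, dtype=float)
            if arr.ndim != 1 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise DegenerateSchemeError("explicit weights must be positive and finite")
        else:
            if self.x < 0:
                raise ValueError("variance offset x must be >= 0")
            if self.p <= 0:
                raise ValueError("exponent p must be > 0")

    def weights(self, data: MetaDataset) -> np.ndarray:
        if self.a is not None:
            arr = np.asarray(self.a, dtype=float)
            if arr.size != data.k:
                raise DegenerateSchemeError(
                    f"scheme has {arr.size} weights for k={data.k} studies"
                )
            return arr
        return 1.0 / (data.v + self.x) ** self.p

    # --- common schemes -------------------------------------------------
    @staticmethod
    def fixed_effect() -> "WeightingScheme":
        """a_i = 1/v_i (Cochran's Q weights)."""
        return WeightingScheme(x=0.0, p=1.0)

    @staticmethod
    def random_effects(tau2: float) -> "WeightingScheme":
        """a_i = 1/(v_i + tau2)."""
        return WeightingScheme(x=float(tau2), p=1.0)

    @staticmethod
    def reciprocal_se() -> "WeightingScheme":
        """a_i = 1/sqrt(v_i) — the default Jackson interval weights."""
        return WeightingScheme(x=0.0, p=0.5)

    @staticmethod
    def from_weights(a) -> "WeightingScheme":
        return WeightingScheme(a=tuple(float(x) for x in a))


@dataclass(frozen=True)
class WeightSums:
    """S_r = sum of FE weights to the r-th power, r = 1, 2, 3."""

    s1: float
    s2: float
    s3: float


def pooled_effect(data: MetaDataset, tau2: float) -> PooledEffect:
    """Inverse-variance pooled effect at a given tau^2 (FE iff tau2 == 0)."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / (data.v + tau2)
    sw = w.sum()
    mu = float(np.dot(w, data.y) / sw)
    return PooledEffect(
        model="FE" if tau2 == 0 else "RE",
        tau2_used=float(tau2),
        mu=mu,
        var_mu=float(1.0 / sw),
        weights=w,
    )


def cochran_q(data: MetaDataset) -> float:
    """Cochran's Q = sum w_i,FE (y_i - mu_FE)^2."""
    w = 1.0 / data.v
    mu = np.dot(w, data.y) / w.sum()
    return float(np.dot(w, (data.y - mu) ** 2))


def generalized_q(data: MetaDataset, scheme: WeightingScheme) -> float:
    """Q_a = sum a_i (y_i - mu_a)^2 with mu_a the a-weighted mean."""
    a = scheme.weights(data)
    if np.any(a <= 0) or not np.all(np.isfinite(a)):
        raise DegenerateSchemeError("weights must be positive and finite")
    mu = np.dot(a, data.y) / a.sum()
    return float(np.dot(a, (data.y - mu) ** 2))


def q_gen(data: MetaDataset, tau2: float) -> float:
    """Q_gen(tau^2): generalised Q with simultaneous RE profiling.

    The pooled mean is recomputed with weights 1/(v_i + tau^2) at each
    candidate value, so Q_gen is strictly decreasing in tau^2 whenever it is
    positive.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / (data.v + tau2)
    mu = np.dot(w, data.y) / w.sum()
    return float(np.dot(w, (data.y - mu) ** 2))


def weight_sums(data: MetaDataset) -> WeightSums:
    w = 1.0 / data.v
    return WeightSums(float(w.sum()), float((w**2).sum()), float((w**3).sum()))


def i_squared(data: MetaDataset) -> float:
    """Higgins–Thompson I² = max(0, (Q - (k-1))/Q) * 100, in [0, 100).

    Defined as 0 when Q = 0 (convention for perfectly homogeneous data).
    """
    q = cochran_q(data)
    if q == 0:
        return 0.0
    return float(max(0.0, (q - (data.k - 1)) / q) * 100.0)
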