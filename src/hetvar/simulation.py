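"""Generative random-effects models and the bias/MSE/coverage harness.

The normal generator draws, per replicate, true study effects
theta_i ~ N(mu, tau^2) and observed effects y_i ~ N(theta_i, v_i) with the
within-study variances v_i treated as known — the textbook random-effects
model.  The binary generator instead simulates 2x2 tables (per-study control
risk, true log odds ratio theta_i), computes the empirical log odds ratio
with a 0.5 continuity correction on zero cells and the Woolf variance, so
that v_i are *estimated*, exercising the known-variance assumption.

Every replicate owns an independent RNG stream keyed by (seed, rep_index),
so results are bit-identical for a fixed seed regardless of evaluation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import EstimatorOptions, MetaDataset
from .registry import estimate as estimate_by_tag
from .registry import interval as interval_by_tag

__all__ = [
    "SimulationScenario",
    "SimulationSummary",
    "scenario_from_config",
    "simulate_normal_meta",
    "simulate_binary_meta",
    "run_estimator_study",
    "run_interval_study",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Configuration of the generative random-effects model.

    v_spec describes the within-study variances: ``("fixed", (v1, ..., vk))``
    uses the given list in every replicate; ``("uniform_fixed", lo, hi)``
    draws v_i once, uniformly, from [lo, hi] (seeded) and holds them fixed
    across replicates — mimicking the known-variances assumption;
    ``("uniform", lo, hi)`` redraws them each replicate.  Binary scenarios
    use arm_size subjects per arm and the stated control-group risk.
    """

    k: int = 10
    mu: float = 0.0
    tau2: float = 0.1
    v_spec: tuple = ("uniform_fixed", 0.05, 0.3)
    n_reps: int = 1000
    seed: int = 0
    outcome_model: str = "normal"
    arm_size: int = 50
    control_risk: float = 0.2

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.outcome_model not in ("normal", "binomial_logOR"):
            raise ValueError("outcome_model must be 'normal' or 'binomial_logOR'")
        kind = self.v_spec[0]
        if kind == "fixed":
            if len(self.v_spec[1]) != self.k or any(v <= 0 for v in self.v_spec[1]):
                raise ValueError("fixed v_spec must list k positive variances")
        elif kind in ("uniform_fixed", "uniform"):
            lo, hi = self.v_spec[1], self.v_spec[2]
            if not (0 < lo <= hi):
                raise ValueError("uniform v_spec needs 0 < lo <= hi")
        else:
            raise ValueError(f"unknown v_spec kind {kind!r}")

    def fixed_variances(self) -> Optional[np.ndarray]:
        """The variances shared by all replicates, if the rule fixes them."""
        kind = self.v_spec[0]
        if kind == "fixed":
            return np.asarray(self.v_spec[1], dtype=float)
        if kind == "uniform_fixed":
            rng = np.random.default_rng([self.seed, 2**20])  # v-draw stream
            return rng.uniform(self.v_spec[1], self.v_spec[2], size=self.k)
        return None


@dataclass(frozen=True)
class SimulationSummary:
    """Per-method bias/MSE table and per-interval coverage table."""

    scenario: SimulationScenario
    estimators: pd.DataFrame      # index: method tag
    intervals: pd.DataFrame       # index: "interval:estimator"
    failures: dict = field(default_factory=dict)


def scenario_from_config(path) -> SimulationScenario:
    """Read a scenario from a flat key: value YAML mapping."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a flat key: value mapping")
    if "v_spec" in raw:
        raw["v_spec"] = tuple(
            tuple(x) if isinstance(x, list) else x for x in raw["v_spec"]
        )
    try:
        return SimulationScenario(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid scenario config: {exc}") from None


def _rep_rng(scn: SimulationScenario, rep_index: int) -> np.random.Generator:
    return np.random.default_rng([scn.seed, rep_index])


def simulate_normal_meta(scn: SimulationScenario, rep_index: int) -> MetaDataset:
    """One replicate dataset under the normal random-effects model."""
    if scn.outcome_model != "normal":
        raise ValueError("scenario is not a normal-outcome scenario")
    rng = _rep_rng(scn, rep_index)
    v = scn.fixed_variances()
    if v is None:
        v = rng.uniform(scn.v_spec[1], scn.v_spec[2], size=scn.k)
    theta = rng.normal(scn.mu, np.sqrt(scn.tau2), size=scn.k)
    y = rng.normal(theta, np.sqrt(v))
    return MetaDataset.from_arrays(y, v)


def simulate_binary_meta(scn: SimulationScenario, rep_index: int) -> MetaDataset:
    """One replicate of 2x2-table meta-analysis data (log odds ratios).

    Zero cells receive a 0.5 continuity correction (all four cells of the
    affected table); double-zero / double-full studies are redrawn with the
    same true effect and the regeneration count is recorded on the dataset
    via the label suffix.
    """
    if scn.outcome_model != "binomial_logOR":
        raise ValueError("scenario is not a binary-outcome scenario")
    rng = _rep_rng(scn, rep_index)
    theta = rng.normal(scn.mu, np.sqrt(scn.tau2), size=scn.k)
    n_arm = scn.arm_size
    p_c = scn.control_risk
    odds_c = p_c / (1 - p_c)
    ys, vs, ns = [], [], []
    for i in range(scn.k):
        p_t = odds_c * np.exp(theta[i]) / (1 + odds_c * np.exp(theta[i]))
        for _attempt in range(1000):
            e_t = rng.binomial(n_arm, p_t)
            e_c = rng.binomial(n_arm, p_c)
            informative = not (
                (e_t == 0 and e_c == 0) or (e_t == n_arm and e_c == n_arm)
            )
            if informative:
                break
        else:
            raise RuntimeError("binary generator: no informative table in 1000 draws")
        cells = np.array([e_t, n_arm - e_t, e_c, n_arm - e_c], dtype=float)
        if np.any(cells == 0):
            cells = cells + 0.5
        a, b, c, d = cells
        ys.append(np.log(a * d / (b * c)))
        vs.append((1 / cells).sum())
        ns.append(2 * n_arm)
    return MetaDataset.from_arrays(ys, vs, n=ns)


def _simulate(scn: SimulationScenario, rep_index: int) -> MetaDataset:
    if scn.outcome_model == "normal":
        return simulate_normal_meta(scn, rep_index)
    return simulate_binary_meta(scn, rep_index)


def run_estimator_study(scn: SimulationScenario, methods: Sequence[str],
                        opts: EstimatorOptions = EstimatorOptions()) -> SimulationSummary:
    """Monte-Carlo bias / MSE / zero-proportion study of point estimators."""
    records = {m: {"tau2": [], "untrunc": []} for m in methods}
    failures = {m: 0 for m in methods}
    for rep in range(scn.n_reps):
        data = _simulate(scn, rep)
        for m in methods:
            try:
                est = estimate_by_tag(m, data, opts)
            except Exception:
                failures[m] += 1
                continue
            records[m]["tau2"].append(est.tau2)
            records[m]["untrunc"].append(est.tau2_untruncated)
    rows = []
    for m in methods:
        t = np.asarray(records[m]["tau2"])
        u = np.asarray(records[m]["untrunc"])
        n = t.size
        if n == 0:
            raise RuntimeError(f"estimator {m} failed in every replicate")
        err = t - scn.tau2
        rows.append({
            "method": m,
            "n_ok": n,
            "mean": t.mean(),
            "bias": err.mean(),
            "bias_se": t.std(ddof=1) / np.sqrt(n),
            "bias_untruncated": (u - scn.tau2).mean(),
            "bias_untruncated_se": u.std(ddof=1) / np.sqrt(n),
            "mse": (err**2).mean(),
            "prop_zero": (t == 0).mean(),
            "failures": failures[m],
        })
    df = pd.DataFrame(rows).set_index("method")
    return SimulationSummary(scenario=scn, estimators=df,
                             intervals=pd.DataFrame(), failures=failures)


def run_interval_study(scn: SimulationScenario,
                       interval_specs: Sequence[tuple],
                       level: float = 0.95,
                       opts: EstimatorOptions = EstimatorOptions(),
                       check_compat: bool = True) -> SimulationSummary:
    """Monte-Carlo coverage / width / tail study of interval methods.

    interval_specs is a list of (interval_tag, estimator_tag) pairs; the
    estimator tag documents the pairing and is validated against the
    compatibility matrix unless check_compat is False.
    """
    from .intervals import compatibility

    if check_compat:
        for iv_tag, est_tag in interval_specs:
            if compatibility(est_tag, iv_tag) == "incompatible":
                raise ValueError(
                    f"({est_tag}, {iv_tag}) is an incompatible pairing; "
                    "pass check_compat=False to override")
    keys = [f"{iv}:{est}" for iv, est in interval_specs]
    rec = {key: {"cover": 0, "low_miss": 0, "high_miss": 0, "degenerate": 0,
                 "width": [], "n_ok": 0}
           for key in keys}
    failures = {key: 0 for key in keys}
    import warnings as _warnings

    for rep in range(scn.n_reps):
        data = _simulate(scn, rep)
        for (iv_tag, est_tag), key in zip(interval_specs, keys):
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    iv = interval_by_tag(iv_tag, data, level, opts)
            except Exception:
                failures[key] += 1
                continue
            r = rec[key]
            r["n_ok"] += 1
            r["width"].append(iv.width)
            if iv.degenerate:
                r["degenerate"] += 1
            if iv.contains(scn.tau2):
                r["cover"] += 1
            elif scn.tau2 < iv.lower:
                r["low_miss"] += 1
            else:
                r["high_miss"] += 1
    rows = []
    for key in keys:
        r = rec[key]
        n = r["n_ok"]
        if n == 0:
            raise RuntimeError(f"interval {key} failed in every replicate")
        cov = r["cover"] / n
        rows.append({
            "pair": key,
            "n_ok": n,
            "coverage": cov,
            "coverage_se": np.sqrt(cov * (1 - cov) / n),
            "miss_low": r["low_miss"] / n,
            "miss_high": r["high_miss"] / n,
            "prop_degenerate": r["degenerate"] / n,
            "mean_width": float(np.mean(r["width"])),
            "failures": failures[key],
        })
    df = pd.DataFrame(rows).set_index("pair")
    return SimulationSummary(scenario=scn, estimators=pd.DataFrame(),
                             intervals=df, failures=failures)
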