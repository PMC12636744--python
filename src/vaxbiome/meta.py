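"""Random-effects meta-analysis of per-cohort feature coefficients.

Inverse-variance pooling with the Paule-Mandel between-cohort variance:
tau^2 solves Q(tau^2) = sum_i w_i (y_i - ybar_w)^2 = k - 1 with
w_i = 1 / (se_i^2 + tau^2), set to 0 when Q(0) <= k - 1.  Features are
pooled only when fitted in at least ``min_cohorts`` cohorts, and the
pooled p-values are Benjamini-Yekutieli adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .diffab import FeatureAssociation, by_fdr
from .errors import ValidationError


@dataclass
class MetaResult:
    feature_id: str
    pooled_coefficient: float
    pooled_se: float
    tau2: float
    z: float
    p_value: float
    q_value: float | None
    k: int
    cohort_effects: dict[str, float] = field(default_factory=dict)
    cohort_ses: dict[str, float] = field(default_factory=dict)


def _validate(effects, std_errors):
    y = np.asarray(effects, dtype=float)
    se = np.asarray(std_errors, dtype=float)
    if y.shape != se.shape or y.ndim != 1:
        raise ValidationError("effects and std_errors must be 1-d and aligned")
    if len(y) < 2:
        raise ValidationError("meta-analysis needs at least 2 cohorts")
    if (se <= 0).any() or not np.isfinite(se).all() or not np.isfinite(y).all():
        raise ValidationError("std_errors must be finite and > 0")
    return y, se


def _q_gen(tau2: float, y: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / (se ** 2 + tau2)
    ybar = (w * y).sum() / w.sum()
    return float((w * (y - ybar) ** 2).sum())


def paule_mandel_tau2(effects, std_errors, tol: float = 1e-10) -> float:
    """Between-cohort variance solving the generalized Q equation."""
    y, se = _validate(effects, std_errors)
    k = len(y)
    target = k - 1
    if _q_gen(0.0, y, se) <= target:
        return 0.0
    # Q is strictly decreasing in tau2; bracket the root then solve
    upper = max(1.0, 10.0 * _dersimonian_laird(y, se))
    while _q_gen(upper, y, se) > target:
        upper *= 2.0
        if upper > 1e12:
            raise ValidationError("Paule-Mandel solver failed to bracket")
    return float(brentq(lambda t: _q_gen(t, y, se) - target, 0.0, upper,
                        xtol=tol, maxiter=200))


def _dersimonian_laird(y: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / se ** 2
    ybar = (w * y).sum() / w.sum()
    q = (w * (y - ybar) ** 2).sum()
    c = w.sum() - (w ** 2).sum() / w.sum()
    return max(0.0, (q - (len(y) - 1)) / c)


def pool_random_effects(effects, std_errors, tau2: float | None = None) -> dict:
    """Inverse-variance random-effects pooling; plain normal z test."""
    y, se = _validate(effects, std_errors)
    if tau2 is None:
        tau2 = paule_mandel_tau2(y, se)
    w = 1.0 / (se ** 2 + tau2)
    pooled = float((w * y).sum() / w.sum())
    pooled_se = float(w.sum() ** -0.5)
    z = pooled / pooled_se
    p = float(2 * norm.sf(abs(z)))
    return {"pooled": pooled, "pooled_se": pooled_se, "tau2": float(tau2),
            "z": float(z), "p_value": p, "k": len(y)}


def meta_analyze(per_cohort: dict[str, list[FeatureAssociation]],
                 min_cohorts: int = 2) -> tuple[list[MetaResult], list[str]]:
    """Pool every feature successfully fitted in >= min_cohorts cohorts.

    Returns (pooled results with BY q-values, excluded feature ids).
    """
    by_feature: dict[str, dict[str, FeatureAssociation]] = {}
    for cohort, results in per_cohort.items():
        for fa in results:
            if fa.skip_reason is None and np.isfinite(fa.p_value) \
                    and np.isfinite(fa.std_error) and fa.std_error > 0:
                by_feature.setdefault(fa.feature_id, {})[cohort] = fa

    pooled: list[MetaResult] = []
    excluded: list[str] = []
    for feature in sorted(by_feature):
        entries = by_feature[feature]
        if len(entries) < min_cohorts:
            excluded.append(feature)
            continue
        cohorts = sorted(entries)
        y = [entries[c].coefficient for c in cohorts]
        se = [entries[c].std_error for c in cohorts]
        r = pool_random_effects(y, se)
        pooled.append(MetaResult(
            feature_id=feature, pooled_coefficient=r["pooled"],
            pooled_se=r["pooled_se"], tau2=r["tau2"], z=r["z"],
            p_value=r["p_value"], q_value=None, k=r["k"],
            cohort_effects=dict(zip(cohorts, map(float, y))),
            cohort_ses=dict(zip(cohorts, map(float, se)))))
    if pooled:
        qs = by_fdr([m.p_value for m in pooled])
        for m, q in zip(pooled, qs):
            m.q_value = float(q)
    return pooled, excluded


def meta_frame(results: list[MetaResult]) -> pd.DataFrame:
    rows = [{
        "feature_id": m.feature_id, "pooled_coefficient": m.pooled_coefficient,
        "pooled_se": m.pooled_se, "tau2": m.tau2, "z": m.z,
        "p_value": m.p_value, "q_value": m.q_value, "k": m.k,
    } for m in results]
    return pd.DataFrame(rows)


def forest_frame(results: list[MetaResult]) -> pd.DataFrame:
    """Long-format rows (per-cohort + pooled) for forest plots."""
    rows = []
    for m in results:
        for cohort in sorted(m.cohort_effects):
            rows.append({"feature_id": m.feature_id, "source": cohort,
                         "coefficient": m.cohort_effects[cohort],
                         "se": m.cohort_ses[cohort]})
        rows.append({"feature_id": m.feature_id, "source": "pooled",
                     "coefficient": m.pooled_coefficient, "se": m.pooled_se})
    return pd.DataFrame(rows)
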