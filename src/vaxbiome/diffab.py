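"""Per-feature differential-abundance regression.

Taxon relative abundances are modelled with a gamma-family, log-link
GLM; gene-family RPK counts with a negative-binomial log-link model
(per-feature ML dispersion, Poisson fallback).  The cluster indicator
codes cluster 0 (non-reactive) as 1, so a positive coefficient means
enrichment in cluster 0 and a negative one enrichment in cluster 1.
P-values are Wald; q-values come from the Benjamini-Yekutieli step-up
over the features actually tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError, ValidationError
from .io import AbundanceTable, CovariateTable, GeneFamilyTable

logger = logging.getLogger("vaxbiome")

CLUSTER_TERM = "cluster0"


@dataclass
class FeatureAssociation:
    feature_id: str
    coefficient: float
    std_error: float
    p_value: float
    q_value: float | None
    n_used: int
    cohort: str
    model: str  # "gamma" | "negbin" | "poisson-fallback"
    prevalence: dict[str, float]
    converged: bool = True
    skip_reason: str | None = None


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(metadata: CovariateTable, cluster: pd.Series,
                 covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Design matrix: intercept, cluster-0 indicator, numeric covariates.

    ``sex`` is coded 0/1 from its categories; missing covariate columns
    raise here (at model construction), not at parse time.
    """
    metadata.require_samples(cluster.index)
    metadata.require_columns(covariates)
    md = metadata.data.loc[cluster.index]
    cl = pd.Series(cluster).astype(int)
    if not cl.isin((0, 1)).all():
        raise ValidationError("cluster labels must be binary")
    x = pd.DataFrame(index=cluster.index)
    x["const"] = 1.0
    x[CLUSTER_TERM] = (cl == 0).astype(float)
    for cov in covariates:
        col = md[cov]
        if col.isna().any():
            raise ModelError(f"covariate {cov!r} has missing values")
        if col.dtype == object or str(col.dtype) == "category":
            codes = pd.Categorical(col).codes.astype(float)
            if len(set(codes)) > 2:
                raise ModelError(f"covariate {cov!r} has >2 categories; "
                                 "encode it numerically upstream")
            x[cov] = codes
        else:
            x[cov] = col.astype(float)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ModelError("design matrix is rank deficient")
    return x


# ---------------------------------------------------------------------------
# single-feature fits
# ---------------------------------------------------------------------------


def _prevalence(detected: np.ndarray, cluster0: np.ndarray) -> dict[str, float]:
    out = {}
    for label, mask in (("cluster0", cluster0 == 1), ("cluster1", cluster0 == 0)):
        out[label] = float(detected[mask].mean()) if mask.any() else 0.0
    return out


def fit_gamma_glm(y, design: pd.DataFrame, feature_id: str = "",
                  cohort: str = "") -> FeatureAssociation:
    """Gamma-family log-link GLM (IRLS); Wald p for the cluster term.

    The response must be strictly positive (handle zeros upstream).
    The dispersion is estimated from Pearson residuals.
    """
    y = np.asarray(y, dtype=float)
    if (y <= 0).any():
        raise ValidationError("gamma response must be strictly positive")
    model = sm.GLM(y, design, family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(scale="X2", maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    coef = float(res.params[CLUSTER_TERM])
    se = float(res.bse[CLUSTER_TERM])
    p = float(res.pvalues[CLUSTER_TERM])
    cluster0 = design[CLUSTER_TERM].to_numpy()
    return FeatureAssociation(
        feature_id=feature_id, coefficient=coef, std_error=se, p_value=p,
        q_value=None, n_used=len(y), cohort=cohort, model="gamma",
        prevalence=_prevalence(y > 0, cluster0), converged=converged)


def fit_negbin_glm(y, design: pd.DataFrame, feature_id: str = "",
                   cohort: str = "") -> FeatureAssociation:
    """Negative-binomial log-link fit with per-feature ML dispersion.

    RPK-like responses are rounded to the nearest integer.  When the
    dispersion estimate collapses to its lower bound (or the NB fit
    fails) a Poisson GLM is used instead.
    """
    y = np.round(np.asarray(y, dtype=float)).astype(int)
    if (y < 0).any():
        raise ValidationError("count response must be non-negative")
    cluster0 = design[CLUSTER_TERM].to_numpy()
    for mask in (cluster0 == 1, cluster0 == 0):
        if mask.any() and y[mask].sum() == 0:
            return FeatureAssociation(
                feature_id=feature_id, coefficient=np.nan, std_error=np.nan,
                p_value=np.nan, q_value=None, n_used=len(y), cohort=cohort,
                model="negbin", prevalence=_prevalence(y > 0, cluster0),
                converged=False, skip_reason="degenerate group")

    model_name = "negbin"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb = sm.NegativeBinomial(y, design)
            fit = nb.fit(disp=0, maxiter=200)
            alpha = float(fit.params[-1])
            if np.isfinite(alpha) and alpha > 1e-6 and fit.mle_retvals.get(
                    "converged", False):
                res = fit
        except Exception:  # noqa: BLE001 - fall through to Poisson
            res = None
        if res is None:
            model_name = "poisson-fallback"
            res = sm.GLM(y, design, family=sm.families.Poisson()).fit()
    coef = float(res.params[CLUSTER_TERM])
    se = float(res.bse[CLUSTER_TERM])
    p = float(res.pvalues[CLUSTER_TERM])
    return FeatureAssociation(
        feature_id=feature_id, coefficient=coef, std_error=se, p_value=p,
        q_value=None, n_used=len(y), cohort=cohort, model=model_name,
        prevalence=_prevalence(y > 0, cluster0), converged=True)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def by_fdr(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values.

    q(i) = min_{j >= i} min(1, p(j) * m * H(m) / j) with H(m) the m-th
    harmonic number, over p sorted ascending.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    harmonic = (1.0 / np.arange(1, m + 1)).sum()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * harmonic / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# per-feature driver
# ---------------------------------------------------------------------------


def run_per_feature(table: AbundanceTable | GeneFamilyTable,
                    metadata: CovariateTable, cluster: pd.Series,
                    model: str = "gamma",
                    covariates: tuple[str, ...] = ("age", "sex"),
                    cohort: str = "",
                    min_prevalence_total: int = 5,
                    min_prevalence_per_cluster: int = 2,
                    zero_replacement: str = "half-min"
                    ) -> list[FeatureAssociation]:
    """Fit one model per feature and attach BY q-values.

    Features failing the prevalence filter (detected in fewer than
    ``min_prevalence_total`` samples overall or fewer than
    ``min_prevalence_per_cluster`` per cluster) are returned with a
    skip reason and no q-value.  Zeros in gamma responses are replaced
    by half the smallest nonzero value of that feature in the cohort.
    """
    if model not in ("gamma", "negbin"):
        raise ValidationError(f"unknown model {model!r}")
    values = table.values
    cluster = pd.Series(cluster).reindex(values.index)
    if cluster.isna().any():
        missing = cluster.index[cluster.isna()][0]
        raise ValidationError(f"sample {missing!r} has no cluster label")
    design = build_design(metadata, cluster.astype(int), covariates)
    cluster0 = design[CLUSTER_TERM].to_numpy()

    results: list[FeatureAssociation] = []
    for feature in values.columns:  # deterministic column order
        y = values[feature].to_numpy(dtype=float)
        detected = y > 0
        per_cluster = [detected[cluster0 == 1].sum(), detected[cluster0 == 0].sum()]
        if (detected.sum() < min_prevalence_total
                or min(per_cluster) < min_prevalence_per_cluster):
            results.append(FeatureAssociation(
                feature_id=str(feature), coefficient=np.nan, std_error=np.nan,
                p_value=np.nan, q_value=None, n_used=len(y), cohort=cohort,
                model=model, prevalence=_prevalence(detected, cluster0),
                converged=False, skip_reason="prevalence filter"))
            continue
        try:
            if model == "gamma":
                if (y == 0).any():
                    if zero_replacement != "half-min":
                        raise ValidationError(
                            f"unknown zero_replacement {zero_replacement!r}")
                    y = np.where(y == 0, y[y > 0].min() / 2.0, y)
                fa = fit_gamma_glm(y, design, feature_id=str(feature),
                                   cohort=cohort)
            else:
                fa = fit_negbin_glm(y, design, feature_id=str(feature),
                                    cohort=cohort)
        except (ModelError, ValidationError):
            raise
        except Exception as exc:  # noqa: BLE001 - skip, do not abort the scan
            logger.warning("feature %s skipped: %s", feature, exc)
            fa = FeatureAssociation(
                feature_id=str(feature), coefficient=np.nan, std_error=np.nan,
                p_value=np.nan, q_value=None, n_used=len(y), cohort=cohort,
                model=model, prevalence=_prevalence(detected, cluster0),
                converged=False, skip_reason=f"fit error: {exc}")
        results.append(fa)

    tested = [fa for fa in results
              if fa.skip_reason is None and np.isfinite(fa.p_value)]
    if tested:
        qs = by_fdr([fa.p_value for fa in tested])
        for fa, q in zip(tested, qs):
            fa.q_value = float(q)
    return results


def associations_frame(results: list[FeatureAssociation]) -> pd.DataFrame:
    rows = []
    for fa in results:
        rows.append({
            "feature_id": fa.feature_id, "coefficient": fa.coefficient,
            "std_error": fa.std_error, "p_value": fa.p_value,
            "q_value": fa.q_value, "n_used": fa.n_used, "cohort": fa.cohort,
            "model": fa.model,
            "prevalence_cluster0": fa.prevalence.get("cluster0"),
            "prevalence_cluster1": fa.prevalence.get("cluster1"),
            "converged": fa.converged, "skip_reason": fa.skip_reason})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.reindex(
            df["coefficient"].abs().sort_values(ascending=False, kind="stable").index)
    return df.reset_index(drop=True)
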