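"""Random-forest prediction benchmarks across cohorts.

Implements repeated stratified cross-validation, training-fold-only
top-k feature selection, leave-one-dataset-out (LODO), the hybrid
X-LODO scheme (cross-validation on a target cohort whose training folds
are augmented with all samples of the other cohorts) and the full
cross-prediction matrix.

Every feature-selection and fitting step is a pure function of
training-fold data; test samples are only ever scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .io import AbundanceTable


@dataclass(frozen=True)
class ForestSettings:
    """Forest hyperparameters (defaults are the benchmark settings)."""

    n_trees: int = 1000
    feature_fraction: float = 0.10
    max_depth: int | None = None
    min_samples_leaf: int = 3
    impurity: str = "gini"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ValidationError("n_trees and min_samples_leaf must be >= 1")
        if not 0 < self.feature_fraction <= 1:
            raise ValidationError("feature_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EvaluationScheme:
    folds: int = 10
    repetitions: int = 10
    stratified: bool = True
    top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


@dataclass
class CVResult:
    """Per-repetition AUCs of a repeated cross-validation."""

    aucs: list[float]
    oof_scores: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class CrossPredictionMatrix:
    """train-cohort x test-cohort AUC grid with LODO / X-LODO rows."""

    cohorts: list[str]
    auc: pd.DataFrame               # index: cohorts + ["LODO", "X-LODO"]
    per_repetition: dict[str, list[float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC, ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# forests and rankings
# ---------------------------------------------------------------------------


def _forest(settings: ForestSettings, random_state: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features=settings.feature_fraction,
        max_depth=settings.max_depth,
        min_samples_leaf=settings.min_samples_leaf,
        criterion=settings.impurity,
        random_state=random_state,
        n_jobs=1)


def _scores(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class."""
    proba = clf.predict_proba(X)
    pos = list(clf.classes_).index(1)
    return proba[:, pos]


def rank_features_training_only(X_train, y_train, settings: ForestSettings,
                                random_state: int | None = None) -> np.ndarray:
    """Feature indices ordered by impurity importance on training data only."""
    rs = settings.seed if random_state is None else random_state
    clf = _forest(settings, rs)
    clf.fit(np.asarray(X_train), np.asarray(y_train).astype(int))
    return np.argsort(-clf.feature_importances_, kind="stable")


def aggregate_rankings(orders: list[np.ndarray], n_features: int) -> np.ndarray:
    """Feature order by mean rank across per-split rankings."""
    mean_rank = np.zeros(n_features)
    for order in orders:
        rank = np.empty(n_features)
        rank[order] = np.arange(n_features)
        mean_rank += rank
    return np.argsort(mean_rank / len(orders), kind="stable")


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------


def _fold_seed(scheme: EvaluationScheme, settings: ForestSettings,
               rep: int, fold: int) -> int:
    return (settings.seed + 1_000_003 * rep + 1_009 * fold) % (2 ** 31 - 1)


def _run_cv(X: np.ndarray, y: np.ndarray, scheme: EvaluationScheme,
            settings: ForestSettings,
            aux_X: np.ndarray | None = None,
            aux_y: np.ndarray | None = None,
            collect_rankings: list[np.ndarray] | None = None) -> CVResult:
    n = len(y)
    if n < scheme.folds:
        raise ValidationError("fewer samples than folds")
    counts = np.bincount(y, minlength=2)
    if scheme.stratified and counts.min() < scheme.folds:
        raise ValidationError(
            f"stratification infeasible: minority class has {counts.min()} "
            f"samples for {scheme.folds} folds; reduce --folds")
    if scheme.top_k is not None and scheme.top_k > X.shape[1]:
        raise ValidationError("top_k exceeds the number of features")

    aucs: list[float] = []
    oof_all: list[np.ndarray] = []
    for r in range(scheme.repetitions):
        # repetition r uses seed = base_seed + r for the fold partition
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True,
                              random_state=scheme.seed + r)
        oof = np.empty(n)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X[tr], y[tr]
            if aux_X is not None:
                X_tr = np.vstack([X_tr, aux_X])
                y_tr = np.concatenate([y_tr, aux_y])
            cols = slice(None)
            rs = _fold_seed(scheme, settings, r, f)
            if scheme.top_k is not None:
                order = rank_features_training_only(X_tr, y_tr, settings,
                                                    random_state=rs)
                if collect_rankings is not None:
                    collect_rankings.append(order)
                # sorted so top_k == n_features reduces to the identity
                cols = np.sort(order[:scheme.top_k])
            clf = _forest(settings, rs)
            clf.fit(X_tr[:, cols], y_tr)
            oof[te] = _scores(clf, X[te][:, cols])
        aucs.append(roc_auc(oof, y))
        oof_all.append(oof)
    return CVResult(aucs=aucs, oof_scores=oof_all)


def repeated_cv(X, y, scheme: EvaluationScheme,
                settings: ForestSettings) -> CVResult:
    """Repeated stratified CV; AUC per repetition on out-of-fold scores."""
    return _run_cv(np.asarray(X, dtype=float), np.asarray(y).astype(int),
                   scheme, settings)


def topk_cv(X, y, scheme: EvaluationScheme, settings: ForestSettings,
            collect_rankings: list[np.ndarray] | None = None) -> CVResult:
    """Repeated CV with training-fold-only top-k feature selection."""
    if scheme.top_k is None:
        raise ValidationError("topk_cv requires scheme.top_k")
    return _run_cv(np.asarray(X, dtype=float), np.asarray(y).astype(int),
                   scheme, settings, collect_rankings=collect_rankings)


# ---------------------------------------------------------------------------
# cohort-transfer schemes
# ---------------------------------------------------------------------------


def harmonize_features(tables: dict[str, AbundanceTable],
                       how: str = "union") -> dict[str, pd.DataFrame]:
    """Align cohort feature spaces: union (absent taxa = 0) or intersection."""
    if how == "union":
        features: list[str] = []
        seen: set[str] = set()
        for t in tables.values():
            for f in t.taxon_ids:
                if f not in seen:
                    seen.add(f)
                    features.append(f)
    elif how == "intersection":
        sets = [set(t.taxon_ids) for t in tables.values()]
        common = set.intersection(*sets)
        features = [f for f in next(iter(tables.values())).taxon_ids
                    if f in common]
        if not features:
            raise ValidationError("no shared features across cohorts")
    else:
        raise ValidationError(f"unknown harmonization {how!r}")
    return {c: t.values.reindex(columns=features, fill_value=0.0)
            for c, t in tables.items()}


def _check_shared_features(datasets: dict[str, tuple[pd.DataFrame, pd.Series]]):
    cols = None
    for cohort, (X, _) in datasets.items():
        if cols is None:
            cols = list(X.columns)
        elif list(X.columns) != cols:
            unshared = set(X.columns).symmetric_difference(cols)
            raise ValidationError(
                f"cohort {cohort!r} feature space mismatch: {sorted(unshared)[:10]}"
                " (use harmonize_features first)")


def lodo(datasets: dict[str, tuple[pd.DataFrame, pd.Series]],
         settings: ForestSettings, top_k: int | None = None) -> dict[str, float]:
    """Train on all-but-one cohort, test on the held-out cohort."""
    if len(datasets) < 2:
        raise ValidationError("LODO needs at least 2 cohorts")
    _check_shared_features(datasets)
    out: dict[str, float] = {}
    for held in datasets:
        X_tr = np.vstack([d[0].to_numpy(dtype=float)
                          for c, d in datasets.items() if c != held])
        y_tr = np.concatenate([np.asarray(d[1]).astype(int)
                               for c, d in datasets.items() if c != held])
        X_te = datasets[held][0].to_numpy(dtype=float)
        y_te = np.asarray(datasets[held][1]).astype(int)
        cols = slice(None)
        if top_k is not None:
            order = rank_features_training_only(X_tr, y_tr, settings)
            cols = np.sort(order[:top_k])
        clf = _forest(settings, settings.seed)
        clf.fit(X_tr[:, cols], y_tr)
        out[held] = roc_auc(_scores(clf, X_te[:, cols]), y_te)
    return out


def xlodo(datasets: dict[str, tuple[pd.DataFrame, pd.Series]],
          scheme: EvaluationScheme, settings: ForestSettings
          ) -> dict[str, CVResult]:
    """CV per target cohort with all other cohorts added to training folds.

    With a single cohort this is exactly plain repeated CV.
    """
    _check_shared_features(datasets)
    out: dict[str, CVResult] = {}
    for target in datasets:
        X = datasets[target][0].to_numpy(dtype=float)
        y = np.asarray(datasets[target][1]).astype(int)
        others = [c for c in datasets if c != target]
        if others:
            aux_X = np.vstack([datasets[c][0].to_numpy(dtype=float)
                               for c in others])
            aux_y = np.concatenate([np.asarray(datasets[c][1]).astype(int)
                                    for c in others])
        else:
            aux_X = aux_y = None
        out[target] = _run_cv(X, y, scheme, settings, aux_X=aux_X, aux_y=aux_y)
    return out


def train_test_auc(train: tuple[pd.DataFrame, pd.Series],
                   test: tuple[pd.DataFrame, pd.Series],
                   settings: ForestSettings, top_k: int | None = None) -> float:
    X_tr = train[0].to_numpy(dtype=float)
    y_tr = np.asarray(train[1]).astype(int)
    cols = slice(None)
    if top_k is not None:
        order = rank_features_training_only(X_tr, y_tr, settings)
        cols = np.sort(order[:top_k])
    clf = _forest(settings, settings.seed)
    clf.fit(X_tr[:, cols], y_tr)
    return roc_auc(_scores(clf, test[0].to_numpy(dtype=float)[:, cols]),
                   np.asarray(test[1]).astype(int))


def cross_prediction_matrix(datasets: dict[str, tuple[pd.DataFrame, pd.Series]],
                            scheme: EvaluationScheme, settings: ForestSettings,
                            small_cohort_folds: dict[str, int] | None = None
                            ) -> CrossPredictionMatrix:
    """Full AUC grid: CV diagonal, train-row/test-column off-diagonal,
    appended LODO and X-LODO rows.

    ``small_cohort_folds`` overrides the fold count per cohort (e.g. 5
    folds for a small cohort).
    """
    if len(datasets) < 2:
        raise ValidationError("cross-prediction needs at least 2 cohorts")
    _check_shared_features(datasets)
    cohorts = list(datasets)
    small_cohort_folds = small_cohort_folds or {}

    def cohort_scheme(cohort: str) -> EvaluationScheme:
        folds = small_cohort_folds.get(cohort, scheme.folds)
        return replace(scheme, folds=folds)

    auc = pd.DataFrame(np.nan, index=cohorts + ["LODO", "X-LODO"],
                       columns=cohorts)
    per_rep: dict[str, list[float]] = {}
    for train_c in cohorts:
        for test_c in cohorts:
            if train_c == test_c:
                cv = _run_cv(datasets[train_c][0].to_numpy(dtype=float),
                             np.asarray(datasets[train_c][1]).astype(int),
                             cohort_scheme(train_c), settings)
                auc.loc[train_c, test_c] = cv.mean_auc
                per_rep[f"cv:{train_c}"] = cv.aucs
            else:
                auc.loc[train_c, test_c] = train_test_auc(
                    datasets[train_c], datasets[test_c], settings,
                    top_k=scheme.top_k)
    for cohort, value in lodo(datasets, settings, top_k=scheme.top_k).items():
        auc.loc["LODO", cohort] = value
    for cohort in cohorts:
        X = datasets[cohort][0].to_numpy(dtype=float)
        y = np.asarray(datasets[cohort][1]).astype(int)
        others = [c for c in cohorts if c != cohort]
        aux_X = np.vstack([datasets[c][0].to_numpy(dtype=float) for c in others])
        aux_y = np.concatenate([np.asarray(datasets[c][1]).astype(int)
                                for c in others])
        cv = _run_cv(X, y, cohort_scheme(cohort), settings,
                     aux_X=aux_X, aux_y=aux_y)
        auc.loc["X-LODO", cohort] = cv.mean_auc
        per_rep[f"xlodo:{cohort}"] = cv.aucs
    return CrossPredictionMatrix(cohorts=cohorts, auc=auc,
                                 per_repetition=per_rep)
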