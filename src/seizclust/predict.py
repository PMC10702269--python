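"""Individualized seizure-type prediction with nested cross-validation.

Per patient and task, five classifier families (logistic regression,
linear-kernel SVM with probability outputs, k-NN, decision tree, random
forest) are evaluated with outer 5-fold stratified cross-validation; inside
each outer training fold an inner 5-fold stratified grid search selects
hyperparameters by mean validation AUC. Classes are weighted inversely
proportional to class size during fitting (where the estimator supports
weighting). Metrics are positive-class precision, recall, F1 and AUC from
the continuous positive-class score.

Two analytic baselines bound the achievable metrics from the class balance
alone. With positive-class prevalence r and a chance predictor that says
"positive" with probability q (0.5 by default):

    baseline 1 (chance):          precision = r, recall = q,
                                  F1 = 2rq/(r+q), AUC = 0.5
    baseline 2 (always positive): precision = r, recall = 1,
                                  F1 = 2r/(r+1), AUC undefined
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ren import feature_columns
from .stats import wilcoxon_cell
from .taxonomy import Task

logger = logging.getLogger(__name__)

MODEL_FAMILIES = (
    "logistic_regression",
    "linear_svm",
    "knn",
    "decision_tree",
    "random_forest",
)

_LOG_C = [0.01, 0.1, 1.0, 10.0, 100.0]

#: Hyperparameter grids: small, standard grids sized to tens-to-hundreds of
#: samples per patient.
DEFAULT_GRIDS: Mapping[str, dict] = {
    "logistic_regression": {"model__C": _LOG_C},
    "linear_svm": {"model__C": _LOG_C},
    "knn": {"model__n_neighbors": [3, 5, 7, 11, 15]},
    "decision_tree": {"model__max_depth": [2, 3, 5, 8, None]},
    "random_forest": {
        "model__n_estimators": [100, 300],
        "model__max_depth": [3, 8, None],
    },
}

#: Families whose decision rule is scale-sensitive (standardized per fold).
_SCALED = {"logistic_regression", "linear_svm", "knn"}


@dataclass(frozen=True)
class CVConfig:
    """Nested stratified cross-validation settings."""

    outer_folds: int = 5
    inner_folds: int = 5
    models: tuple[str, ...] = MODEL_FAMILIES
    grids: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    q_baseline: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.models) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        for m in self.models:
            if not self.grids.get(m):
                raise ValueError(f"empty hyperparameter grid for {m}")


def _make_estimator(family: str, seed: int) -> Pipeline:
    if family == "logistic_regression":
        model = LogisticRegression(class_weight="balanced", max_iter=5000)
    elif family == "linear_svm":
        model = SVC(
            kernel="linear", probability=True, class_weight="balanced",
            random_state=seed,
        )
    elif family == "knn":
        # k-NN has no notion of per-sample weight; it is fit unweighted.
        model = KNeighborsClassifier()
    elif family == "decision_tree":
        model = DecisionTreeClassifier(class_weight="balanced", random_state=seed)
    elif family == "random_forest":
        model = RandomForestClassifier(class_weight="balanced", random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    steps = []
    if family in _SCALED:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", model))
    return Pipeline(steps)


@dataclass
class EvalReport:
    """Per-fold metrics for one patient and task, all model families.

    ``folds`` has one row per (model, fold) with precision, recall, f1, auc
    (NaN-flagged when the test fold is single-class); ``aggregate()`` gives
    the cross-fold mean and SD per model.
    """

    patient_id: str
    task: str
    folds: pd.DataFrame
    baselines: "BaselinePerformance"

    def aggregate(self) -> pd.DataFrame:
        agg = self.folds.groupby("model")[["precision", "recall", "f1", "auc"]].agg(
            ["mean", "std"]
        )
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()


@dataclass(frozen=True)
class BaselinePerformance:
    """Closed-form metrics of the two analytic baselines.

    ``r`` is the positive-class prevalence, ``q`` the chance predictor's
    positive-prediction probability.
    """

    r: float
    q: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError("prevalence r must lie strictly in (0, 1)")
        if not 0 < self.q <= 1:
            raise ValueError("q must lie in (0, 1]")

    @classmethod
    def from_counts(cls, n_negative: int, n_positive: int, q: float = 0.5) -> "BaselinePerformance":
        total = n_negative + n_positive
        if total == 0:
            raise ValueError("no samples")
        return cls(r=n_positive / total, q=q)

    # baseline 1: chance-level predictor
    @property
    def precision_b1(self) -> float:
        return self.r

    @property
    def recall_b1(self) -> float:
        return self.q

    @property
    def f1_b1(self) -> float:
        return 2 * self.r * self.q / (self.r + self.q)

    @property
    def auc_b1(self) -> float:
        return 0.5

    # baseline 2: always predicts positive
    @property
    def precision_b2(self) -> float:
        return self.r

    @property
    def recall_b2(self) -> float:
        return 1.0

    @property
    def f1_b2(self) -> float:
        return 2 * self.r / (self.r + 1.0)

    auc_b2 = None  # AUC of a constant predictor is undefined

    def as_percent_row(self) -> dict[str, float]:
        """All metrics as percentages rounded to 1 decimal (table style)."""
        return {
            "precision_b1": round(100 * self.precision_b1, 1),
            "recall_b1": round(100 * self.recall_b1, 1),
            "f1_b1": round(100 * self.f1_b1, 1),
            "auc_b1": round(100 * self.auc_b1, 1),
            "precision_b2": round(100 * self.precision_b2, 1),
            "recall_b2": round(100 * self.recall_b2, 1),
            "f1_b2": round(100 * self.f1_b2, 1),
        }


def baseline_performance(r: float, q: float = 0.5) -> BaselinePerformance:
    """Analytic baseline metrics for prevalence ``r`` and chance rate ``q``."""
    return BaselinePerformance(r=r, q=q)


def _task_arrays(
    features: pd.DataFrame, task: Task, bands: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (X, y) for one patient's feature table and task."""
    if bands is None:
        cols = [c for c in features.columns if c.startswith("ga_ren_")]
    else:
        cols = feature_columns(bands)
    sub = features.dropna(subset=cols)
    if len(sub) < len(features):
        logger.info("dropped %d rows with missing features", len(features) - len(sub))
    if task == "next_seizure":
        y = (sub.category == "cluster_non_last").astype(int).to_numpy()
        X = sub[cols].to_numpy()
    elif task == "cluster_onset":
        keep = sub.is_cluster_first | (sub.category == "isolated")
        sub = sub[keep]
        y = sub.is_cluster_first.astype(int).to_numpy()
        X = sub[cols].to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}")
    return X, y


def _fit_fold(
    family: str,
    grid: dict,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    inner_folds: int,
    seed: int,
) -> Pipeline:
    """Inner stratified grid search on the outer-training portion only."""
    est = _make_estimator(family, seed)
    n_min = int(np.bincount(y_tr).min())
    k = min(inner_folds, max(2, n_min))
    inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + 1)
    search = GridSearchCV(
        est, grid, scoring="roc_auc", cv=inner, n_jobs=1, error_score=np.nan,
        refit=True,
    )
    search.fit(X_tr, y_tr)
    return search.best_estimator_


def _score(est: Pipeline, X: np.ndarray) -> np.ndarray:
    return est.predict_proba(X)[:, 1]


def run_task(
    features: pd.DataFrame,
    task: Task,
    cfg: CVConfig | None = None,
    bands: Sequence[str] | None = None,
) -> EvalReport:
    """Nested-CV evaluation of all model families for one patient and task."""
    cfg = cfg or CVConfig()
    pid = str(features.patient_id.iloc[0])
    X, y = _task_arrays(features, task, bands)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.outer_folds:
        raise ValueError(
            f"patient {pid}: class counts {counts.tolist()} too small for "
            f"{cfg.outer_folds}-fold stratified CV"
        )
    outer = StratifiedKFold(
        n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed
    )
    rows = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        for family in cfg.models:
            est = _fit_fold(
                family, cfg.grids[family], X[tr], y[tr], cfg.inner_folds, cfg.seed
            )
            score = _score(est, X[te])
            pred = est.predict(X[te])
            single_class = len(np.unique(y[te])) < 2
            if single_class:
                logger.info("patient %s fold %d: single-class test fold", pid, fold)
            rows.append(
                {
                    "model": family,
                    "fold": fold,
                    "precision": precision_score(y[te], pred, zero_division=0),
                    "recall": recall_score(y[te], pred, zero_division=0),
                    "f1": f1_score(y[te], pred, zero_division=0),
                    "auc": np.nan if single_class else roc_auc_score(y[te], score),
                }
            )
    baselines = BaselinePerformance.from_counts(
        int(counts[0]), int(counts[1]), q=cfg.q_baseline
    )
    return EvalReport(pid, task, pd.DataFrame(rows), baselines)


def sample_size_sweep(
    features: pd.DataFrame,
    task: Task,
    cfg: CVConfig | None = None,
    schedule: str = "fractions",
    model: str = "random_forest",
    n_repeats: int = 5,
    test_fraction: float = 0.2,
    tune: bool = False,
) -> pd.DataFrame:
    """Test AUC vs training-set size on a fixed stratified test split.

    ``schedule='fractions'`` trains on {20, 40, 60, 80, 100}% of the
    training pool; ``'powers'`` on 2^y samples for y in 4..9, capped at the
    pool size. Each size is re-sampled ``n_repeats`` times with
    stratification; mean and SD AUC over the repeats are reported.
    """
    cfg = cfg or CVConfig()
    X, y = _task_arrays(features, task)
    rng = np.random.default_rng(cfg.seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=cfg.seed
    )
    n_pool = len(y_tr)
    if schedule == "fractions":
        sizes = [max(4, int(round(n_pool * f / 100))) for f in (20, 40, 60, 80, 100)]
        labels = [20, 40, 60, 80, 100]
    elif schedule == "powers":
        labels = [2**yy for yy in range(4, 10)]
        sizes = []
        for s in labels:
            if s > n_pool:
                logger.warning("requested %d training samples > pool %d; capped", s, n_pool)
            sizes.append(min(s, n_pool))
    else:
        raise ValueError(f"unknown schedule {schedule!r}")

    rows = []
    for label, size in zip(labels, sizes):
        aucs = []
        # the model seed is held fixed so only the subsample varies between
        # repetitions; at 100% the subset is unique and the SD is exactly 0
        reps = 1 if size >= n_pool else n_repeats
        for _ in range(reps):
            if size >= n_pool:
                idx = np.arange(n_pool)
            else:
                idx = _stratified_subset(y_tr, size, rng)
            if len(np.unique(y_tr[idx])) < 2:
                continue
            if tune:
                est = _fit_fold(
                    model, cfg.grids[model], X_tr[idx], y_tr[idx], cfg.inner_folds,
                    cfg.seed,
                )
            else:
                est = _make_estimator(model, cfg.seed)
                est.fit(X_tr[idx], y_tr[idx])
            aucs.append(roc_auc_score(y_te, _score(est, X_te)))
        rows.append(
            {
                "size_label": label,
                "n_train": size,
                "auc_mean": float(np.mean(aucs)) if aucs else np.nan,
                "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "n_repeats": len(aucs),
            }
        )
    return pd.DataFrame(rows)


def _stratified_subset(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Class-proportional subsample of indices (at least one per class)."""
    idx_parts = []
    classes, counts = np.unique(y, return_counts=True)
    quota = np.maximum(1, np.round(size * counts / counts.sum()).astype(int))
    # trim rounding surplus from the majority class
    while quota.sum() > size:
        quota[np.argmax(quota)] -= 1
    for cls, k in zip(classes, quota):
        pool = np.flatnonzero(y == cls)
        idx_parts.append(rng.choice(pool, size=min(k, pool.size), replace=False))
    return np.concatenate(idx_parts)


def characteristic_association(
    auc_by_patient: Mapping[str, float],
    patient_table: pd.DataFrame,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
) -> pd.DataFrame:
    """Associate per-patient AUC with patient characteristics.

    Categorical variables: two-sided Wilcoxon rank-sum between the two
    groups (marked untestable if any group has < 2 patients or there are
    more than two groups). Continuous variables: Spearman rank correlation.
    ``patient_table`` must be indexed by (or contain) ``patient_id``.
    """
    table = patient_table.copy()
    if "patient_id" in table.columns:
        table = table.set_index("patient_id")
    aucs = pd.Series(auc_by_patient, dtype=float)
    table = table.loc[aucs.index]
    rows = []
    for col in categorical:
        levels = table[col].dropna().unique()
        if len(levels) != 2:
            rows.append({"characteristic": col, "kind": "categorical",
                         "statistic": np.nan, "p": np.nan, "testable": False})
            continue
        g0 = aucs[table[col] == levels[0]].to_numpy()
        g1 = aucs[table[col] == levels[1]].to_numpy()
        if min(g0.size, g1.size) < 2:
            rows.append({"characteristic": col, "kind": "categorical",
                         "statistic": np.nan, "p": np.nan, "testable": False})
            continue
        p, _ = wilcoxon_cell(g0, g1)
        rows.append({"characteristic": col, "kind": "categorical",
                     "statistic": np.nan, "p": float(p), "testable": True})
    for col in continuous:
        vals = table[col].astype(float).to_numpy()
        if np.unique(vals).size < 2:
            rows.append({"characteristic": col, "kind": "continuous",
                         "statistic": np.nan, "p": np.nan, "testable": False})
            continue
        rho, p = sstats.spearmanr(vals, aucs.to_numpy())
        rows.append({"characteristic": col, "kind": "continuous",
                     "statistic": float(rho), "p": float(p), "testable": True})
    return pd.DataFrame(rows)
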