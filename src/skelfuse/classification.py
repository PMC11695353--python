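"""Two-phase nested cross-validated maximum-margin classification.

Phase 1 tunes a support-vector classifier on a single anchor metric with a
stratified 5x5 nested cross-validation: per outer fold the features are
min-max scaled to [0, 1] on the learning set only (test fold scaled with the
learning-set parameters and clipped), an inner stratified grid search selects
the penalty C, the kernel and the univariate feature fraction by mean inner F1,
the winner is refit on the learning set and scored on the held-out fold.
Consensus hyperparameters are the modal choices across outer folds.

Phase 2 re-evaluates every other metric under the fixed consensus
hyperparameters with the same outer cross-validation but no inner search,
keeping the comparison across metrics controlled.

For linear kernels the per-fold weight vectors (the SVM coefficients of the
discriminant hyperplane, mapped back through the feature selector) are
averaged across folds, rectified and min-max normalized to a [0, 1] relevance
map over skeleton voxels.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectPercentile, f_classif
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .data_model import CohortDataset, SkeletonMask

logger = logging.getLogger(__name__)

KERNEL_ORDER = ("linear", "rbf", "poly")  # simpler first, for tie-breaking

SCORE_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclasses.dataclass(frozen=True)
class HyperparamGrid:
    """Search grid for phase 1 (defaults follow the study design)."""

    C_values: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1e6)
    kernels: tuple[str, ...] = ("linear", "rbf", "poly")
    feature_fractions: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0)

    def __post_init__(self) -> None:
        if not (self.C_values and self.kernels and self.feature_fractions):
            raise ValueError("grid lists must be non-empty")
        if any(c <= 0 for c in self.C_values):
            raise ValueError("C values must be positive")
        if any(k not in KERNEL_ORDER for k in self.kernels):
            raise ValueError(f"kernels must be among {KERNEL_ORDER}")
        if any(not 0 < f <= 100 for f in self.feature_fractions):
            raise ValueError("feature fractions must be in (0, 100]")


@dataclasses.dataclass
class FoldResult:
    fold_index: int
    chosen_params: tuple[float, str, float]  # (C, kernel, fraction %)
    scores: dict[str, float]
    weight_vector: np.ndarray | None  # length-M, linear kernel only


@dataclasses.dataclass
class ClassificationReport:
    metric: str
    folds: list[FoldResult]
    mean_scores: dict[str, float]
    sd_scores: dict[str, float]
    consensus_params: tuple[float, str, float] | None = None
    weight_map: np.ndarray | None = None  # normalized [0,1], linear only


def compute_binary_metrics(
    scores: Sequence[float], labels: Sequence[int]
) -> dict[str, float]:
    """Threshold-at-zero confusion metrics plus tie-aware rank AUC.

    ``labels`` is the 0/1 encoding with group A (preterm-like) positive;
    ``scores`` are signed decision values (positive predicts the positive
    class).  AUC is the rank statistic P(score_pos > score_neg) with ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pred = (scores > 0).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / y.size
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "auc": float(auc),
    }


def _minmax_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return lo, rng


def _minmax_apply(x: np.ndarray, lo: np.ndarray, rng: np.ndarray) -> np.ndarray:
    return np.clip((x - lo) / rng, 0.0, 1.0)


def _make_svc(c: float, kernel: str) -> SVC:
    return SVC(C=c, kernel=kernel, degree=3, gamma="scale")


def _fold_weights(
    pipeline: Pipeline, n_features: int
) -> np.ndarray:
    svc: SVC = pipeline.named_steps["svc"]
    selector: SelectPercentile = pipeline.named_steps["select"]
    w = np.zeros(n_features)
    w[selector.get_support()] = svc.coef_.ravel()
    return w


class NestedCVClassifier(BaseEstimator):
    """Phase-1 nested stratified cross-validated SVM (sklearn-style).

    ``fit(X, y)`` runs the full nested design on an ``(n_subjects,
    n_features)`` matrix with 0/1 labels (1 = positive class) and exposes
    ``folds_``, ``mean_scores_``, ``sd_scores_``, ``consensus_params_`` and,
    when the consensus kernel is linear, ``weight_map_``.
    """

    def __init__(
        self,
        grid: HyperparamGrid | None = None,
        k_outer: int = 5,
        k_inner: int = 5,
        random_state: int | None = 0,
    ) -> None:
        self.grid = grid
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NestedCVClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        grid = self.grid or HyperparamGrid()
        counts = np.bincount(y, minlength=2)
        if counts.min() < self.k_outer:
            raise ValueError(
                f"each class needs >= k_outer={self.k_outer} subjects, "
                f"got counts {counts.tolist()}"
            )
        outer = StratifiedKFold(
            n_splits=self.k_outer, shuffle=True, random_state=self.random_state
        )
        # one block per kernel, simplest first: GridSearchCV resolves inner-F1
        # ties by candidate order, so ties prefer linear > rbf > poly, then
        # the earlier feature fraction and the smaller C
        param_grid = [
            {
                "svc__kernel": [kernel],
                "select__percentile": list(grid.feature_fractions),
                "svc__C": list(grid.C_values),
            }
            for kernel in sorted(grid.kernels, key=KERNEL_ORDER.index)
        ]
        folds: list[FoldResult] = []
        for fold_i, (learn_idx, test_idx) in enumerate(outer.split(X, y)):
            y_learn, y_test = y[learn_idx], y[test_idx]
            if len(np.unique(y_learn)) < 2 or len(np.unique(y_test)) < 2:
                raise ValueError(f"degenerate single-class outer fold {fold_i}")
            lo, rng = _minmax_fit(X[learn_idx])
            x_learn = _minmax_apply(X[learn_idx], lo, rng)
            x_test = _minmax_apply(X[test_idx], lo, rng)
            inner = StratifiedKFold(
                n_splits=self.k_inner,
                shuffle=True,
                random_state=None
                if self.random_state is None
                else self.random_state + fold_i + 1,
            )
            pipe = Pipeline(
                [
                    ("select", SelectPercentile(f_classif)),
                    ("svc", _make_svc(1.0, "linear")),
                ]
            )
            search = GridSearchCV(
                pipe, param_grid, scoring="f1", cv=inner, refit=True, n_jobs=None
            )
            with warnings.catch_warnings():
                # constant features under min-max scaling trip f_classif
                warnings.simplefilter("ignore")
                search.fit(x_learn, y_learn)
            best = search.best_params_
            chosen = (
                float(best["svc__C"]),
                str(best["svc__kernel"]),
                float(best["select__percentile"]),
            )
            dec = search.best_estimator_.decision_function(x_test)
            scores = compute_binary_metrics(dec, y_test)
            weight = (
                _fold_weights(search.best_estimator_, X.shape[1])
                if chosen[1] == "linear"
                else None
            )
            folds.append(FoldResult(fold_i, chosen, scores, weight))
            logger.info(
                "phase1 fold %d: params=%s scores=%s", fold_i, chosen,
                {k: round(v, 3) for k, v in scores.items()},
            )
        self.folds_ = folds
        self.mean_scores_ = {
            s: float(np.mean([f.scores[s] for f in folds])) for s in SCORE_NAMES
        }
        self.sd_scores_ = {
            s: float(np.std([f.scores[s] for f in folds])) for s in SCORE_NAMES
        }
        self.consensus_params_ = consensus_hyperparams_from_folds(folds, grid)
        if self.consensus_params_[1] == "linear" and all(
            f.weight_vector is not None for f in folds
        ):
            self.weight_map_ = _normalize_weights(
                [f.weight_vector for f in folds]
            )
        else:
            self.weight_map_ = None
        return self

    def report(self, metric: str = "") -> ClassificationReport:
        return ClassificationReport(
            metric=metric,
            folds=self.folds_,
            mean_scores=self.mean_scores_,
            sd_scores=self.sd_scores_,
            consensus_params=self.consensus_params_,
            weight_map=self.weight_map_,
        )


class FixedParamsCV(BaseEstimator):
    """Phase-2 stratified CV under fixed hyperparameters (no inner search)."""

    def __init__(
        self,
        C: float = 1.0,
        kernel: str = "linear",
        feature_fraction: float = 100.0,
        k: int = 5,
        random_state: int | None = 0,
    ) -> None:
        self.C = C
        self.kernel = kernel
        self.feature_fraction = feature_fraction
        self.k = k
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FixedParamsCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.bincount(y, minlength=2).min() < self.k:
            raise ValueError(f"each class needs >= k={self.k} subjects")
        cv = StratifiedKFold(
            n_splits=self.k, shuffle=True, random_state=self.random_state
        )
        folds: list[FoldResult] = []
        params = (float(self.C), str(self.kernel), float(self.feature_fraction))
        for fold_i, (learn_idx, test_idx) in enumerate(cv.split(X, y)):
            if len(np.unique(y[test_idx])) < 2:
                raise ValueError(f"degenerate single-class fold {fold_i}")
            lo, rng = _minmax_fit(X[learn_idx])
            x_learn = _minmax_apply(X[learn_idx], lo, rng)
            x_test = _minmax_apply(X[test_idx], lo, rng)
            pipe = Pipeline(
                [
                    ("select", SelectPercentile(f_classif, percentile=params[2])),
                    ("svc", _make_svc(params[0], params[1])),
                ]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(x_learn, y[learn_idx])
            dec = pipe.decision_function(x_test)
            scores = compute_binary_metrics(dec, y[test_idx])
            weight = (
                _fold_weights(pipe, X.shape[1])
                if params[1] == "linear"
                else None
            )
            folds.append(FoldResult(fold_i, params, scores, weight))
        self.folds_ = folds
        self.mean_scores_ = {
            s: float(np.mean([f.scores[s] for f in folds])) for s in SCORE_NAMES
        }
        self.sd_scores_ = {
            s: float(np.std([f.scores[s] for f in folds])) for s in SCORE_NAMES
        }
        self.weight_map_ = (
            _normalize_weights([f.weight_vector for f in folds])
            if params[1] == "linear"
            else None
        )
        return self

    def report(self, metric: str = "") -> ClassificationReport:
        return ClassificationReport(
            metric=metric,
            folds=self.folds_,
            mean_scores=self.mean_scores_,
            sd_scores=self.sd_scores_,
            consensus_params=(self.C, self.kernel, self.feature_fraction),
            weight_map=self.weight_map_,
        )


def consensus_hyperparams_from_folds(
    folds: Sequence[FoldResult],
    grid: HyperparamGrid | None = None,
    feature_fraction: float = 100.0,
) -> tuple[float, str, float]:
    """Modal C and kernel across folds; ties -> smaller C / simpler kernel.

    The feature fraction is fixed at 100% by default (univariate selection is
    not beneficial in this design); pass ``feature_fraction`` to override.
    """
    if not folds:
        raise ValueError("need at least one fold")
    c_vals = [f.chosen_params[0] for f in folds]
    kernels = [f.chosen_params[1] for f in folds]
    c_mode = max(sorted(set(c_vals)), key=lambda c: (c_vals.count(c), -c))
    kern_mode = max(
        sorted(set(kernels), key=KERNEL_ORDER.index),
        key=lambda k: (kernels.count(k), -KERNEL_ORDER.index(k)),
    )
    return (float(c_mode), kern_mode, float(feature_fraction))


def consensus_hyperparams(
    report: ClassificationReport,
    grid: HyperparamGrid | None = None,
    feature_fraction: float = 100.0,
) -> tuple[float, str, float]:
    return consensus_hyperparams_from_folds(report.folds, grid, feature_fraction)


def _normalize_weights(weights: Sequence[np.ndarray]) -> np.ndarray:
    mean_w = np.mean(np.vstack(weights), axis=0)
    abs_w = np.abs(mean_w)
    span = abs_w.max() - abs_w.min()
    if span == 0:
        warnings.warn(
            "degenerate weight map: fold-averaged weights are constant "
            "(possible cancellation); returning zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(abs_w)
    return (abs_w - abs_w.min()) / span


def extract_weight_map(
    report: ClassificationReport, mask: SkeletonMask | None = None
) -> np.ndarray:
    """Fold-averaged, rectified, [0,1]-normalized linear-SVM weight map."""
    if any(f.chosen_params[1] != "linear" for f in report.folds):
        raise ValueError("weight maps are defined for the linear kernel only")
    if any(f.weight_vector is None for f in report.folds):
        raise ValueError("fold weight vectors missing")
    wmap = _normalize_weights([f.weight_vector for f in report.folds])
    if mask is not None and wmap.shape != (mask.n_voxels,):
        raise ValueError("weight map length does not match mask voxel count")
    return wmap


# -- dataset-level wrappers --------------------------------------------------


def nested_cv_phase1(
    dataset: CohortDataset,
    metric: str,
    grid: HyperparamGrid | None = None,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int | None = 0,
) -> ClassificationReport:
    est = NestedCVClassifier(
        grid=grid, k_outer=k_outer, k_inner=k_inner, random_state=seed
    )
    est.fit(dataset.metrics[metric], dataset.binary_labels())
    return est.report(metric)


def evaluate_phase2(
    dataset: CohortDataset,
    metric: str,
    fixed_params: tuple[float, str, float],
    k: int = 5,
    seed: int | None = 0,
) -> ClassificationReport:
    c, kernel, fraction = fixed_params
    est = FixedParamsCV(
        C=c, kernel=kernel, feature_fraction=fraction, k=k, random_state=seed
    )
    est.fit(dataset.metrics[metric], dataset.binary_labels())
    return est.report(metric)
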