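"""RBF-kernel SVM separating TSS chromatin profiles from random-region profiles.

The classifier is the standard soft-margin SVM with decision function
``sgn(sum_i y_i a_i K(x_i, x) + rho)`` and RBF kernel
``K(u, v) = exp(-gamma ||u - v||^2)``.  The penalty ``C`` and kernel width
``gamma`` are selected by cross-validated grid search on the training half
only; features are standardised (fit on the training half) because the RBF
kernel is scale-sensitive.  A Platt-style one-dimensional logistic map fitted
on training decision scores converts scores to probabilities; only its strict
monotonicity in the decision score is relied on downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .profiles import Anchor, ProfileMatrix, build_matrix

__all__ = [
    "SvmConfig",
    "TrainedClassifier",
    "RocResult",
    "split_half",
    "train_svm",
    "predict_scores",
    "roc_auc",
    "evaluate_windows",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SvmConfig:
    """Grid-search and preprocessing settings for SVM training."""

    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1)
    cv_folds: int = 5
    seed: int = 0
    class_weighting: str = "none"  # or "balanced"
    scaling: str = "standardize"  # or "none"

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.class_weighting not in {"none", "balanced"}:
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.scaling not in {"none", "standardize"}:
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass
class TrainedClassifier:
    """Fitted scaler + RBF-SVM + score->probability calibration."""

    C: float
    gamma: float
    pipeline: Pipeline
    calibrator: LogisticRegression
    n_features: int
    cv_accuracy: float
    config: SvmConfig

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match training width {self.n_features}"
            )
        return self.pipeline.decision_function(X)

    def probability(self, scores: np.ndarray) -> np.ndarray:
        return self.calibrator.predict_proba(np.asarray(scores).reshape(-1, 1))[:, 1]


@dataclass
class RocResult:
    """ROC curve and area under it."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def split_half(matrix: ProfileMatrix, seed: int) -> tuple[ProfileMatrix, ProfileMatrix]:
    """Stratified random 50/50 split into training and testing halves.

    Odd class sizes put the extra row in the test half (floor on the training
    side).  The two halves partition the input rows.
    """
    if matrix.y is None:
        raise ValueError("split_half requires labels")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (-1, 1):
        rows = np.flatnonzero(matrix.y == cls)
        if len(rows) < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 members")
        rows = rng.permutation(rows)
        n_train = len(rows) // 2
        train_idx.extend(rows[:n_train])
        test_idx.extend(rows[n_train:])
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(test_idx))


def _make_pipeline(config: SvmConfig, C: float, gamma: float) -> Pipeline:
    steps = []
    if config.scaling == "standardize":
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel="rbf",
                C=C,
                gamma=gamma,
                class_weight=None if config.class_weighting == "none" else "balanced",
            ),
        )
    )
    return Pipeline(steps)


def train_svm(train: ProfileMatrix, config: SvmConfig | None = None) -> TrainedClassifier:
    """Grid-search (C, gamma) by CV accuracy on the training half, then refit.

    Ties are broken toward the smallest C, then the smallest gamma.  The final
    model is refit on the full training half and a Platt-style sigmoid is
    fitted on its decision scores.
    """
    config = config or SvmConfig()
    if train.y is None:
        raise ValueError("training matrix has no labels")
    X, y = np.asarray(train.X, dtype=np.float64), train.y
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    for C, gamma in itertools.product(config.C_grid, config.gamma_grid):
        accs = []
        for tr, va in folds:
            pipe = _make_pipeline(config, C, gamma)
            pipe.fit(X[tr], y[tr])
            accs.append(np.mean(pipe.predict(X[va]) == y[va]))
        acc = float(np.mean(accs))
        if best is None or acc > best[0] + 1e-12:
            best = (acc, C, gamma)
    assert best is not None
    cv_acc, C, gamma = best

    pipe = _make_pipeline(config, C, gamma)
    pipe.fit(X, y)
    scores = pipe.decision_function(X)
    calibrator = LogisticRegression(C=1e6)
    if len(np.unique(scores)) == 1:
        # degenerate: constant scores; fit on jittered copy to stay monotone
        scores = scores + np.linspace(-1e-9, 1e-9, len(scores))
    calibrator.fit(scores.reshape(-1, 1), y)
    return TrainedClassifier(
        C=C,
        gamma=gamma,
        pipeline=pipe,
        calibrator=calibrator,
        n_features=X.shape[1],
        cv_accuracy=cv_acc,
        config=config,
    )


def predict_scores(
    model: TrainedClassifier, matrix: ProfileMatrix | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and calibrated probabilities, row by row."""
    X = matrix.X if isinstance(matrix, ProfileMatrix) else np.asarray(matrix)
    scores = model.decision_function(X)
    return scores, model.probability(scores)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve by threshold sweep; AUC equals the tie-corrected rank statistic
    P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def evaluate_windows(
    tracks,
    pos_anchors: Sequence[Anchor],
    neg_anchors: Sequence[Anchor],
    marks_subsets: Sequence[Sequence[str]],
    k_list: Sequence[int] = (20, 15, 10, 5),
    seed: int = 0,
    config: SvmConfig | None = None,
) -> pd.DataFrame:
    """Held-out AUC per (mark subset, window half-width k).

    For every subset of marks and every ``k``, the labelled profile matrix is
    split in half, the SVM is tuned and trained on one half and the AUC of its
    decision scores on the other half is reported — one row per combination.
    """
    if len(pos_anchors) == 0 or len(neg_anchors) == 0:
        raise ValueError("need both positive and negative anchors")
    config = config or SvmConfig(seed=seed)
    anchors = list(pos_anchors) + list(neg_anchors)
    labels = [1] * len(pos_anchors) + [-1] * len(neg_anchors)
    rows = []
    for marks in marks_subsets:
        marks = list(marks)
        for k in k_list:
            matrix = build_matrix(tracks, anchors, labels, k=k, marks=marks)
            train, test = split_half(matrix, seed=seed)
            model = train_svm(train, config)
            scores, _ = predict_scores(model, test)
            res = roc_auc(scores, test.y)
            rows.append(
                {
                    "marks": "+".join(marks),
                    "n_marks": len(marks),
                    "k": k,
                    "auc": res.auc,
                    "C": model.C,
                    "gamma": model.gamma,
                    "cv_accuracy": model.cv_accuracy,
                }
            )
    return pd.DataFrame(rows)


def save_model(model: TrainedClassifier, path) -> None:
    """Persist a trained classifier (format version, config, scaler, SVM,
    calibration) with joblib."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "C": model.C,
            "gamma": model.gamma,
            "pipeline": model.pipeline,
            "calibrator": model.calibrator,
            "n_features": model.n_features,
            "cv_accuracy": model.cv_accuracy,
            "config": model.config,
        },
        path,
    )


def load_model(path) -> TrainedClassifier:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {blob.get('format_version')}")
    return TrainedClassifier(
        C=blob["C"],
        gamma=blob["gamma"],
        pipeline=blob["pipeline"],
        calibrator=blob["calibrator"],
        n_features=blob["n_features"],
        cv_accuracy=blob["cv_accuracy"],
        config=blob["config"],
    )
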