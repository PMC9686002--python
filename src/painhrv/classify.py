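"""Leave-one-subject-out classification of baseline vs. cold-pressor epochs.

The pipeline per fold is standardize -> PCA -> L2 logistic regression, fit
on all subjects but one and evaluated on the held-out subject; held-out
predictions are pooled over folds before per-class precision, recall, F1
and support are computed.  Two feature configurations are supported:
``laboratory`` (all 46 features) and ``field`` (the 18 time-domain HRV
features a wearable could supply).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, InvalidDatasetError
from .features import FEATURE_NAMES, TIME_DOMAIN_FEATURES

logger = logging.getLogger(__name__)

CLASSES = ("BL", "CPT")

FEATURE_SETS = {
    "laboratory": list(FEATURE_NAMES),
    "field": list(TIME_DOMAIN_FEATURES),
}


@dataclass(frozen=True)
class ModelConfig:
    """Classifier configuration.

    ``feature_set`` selects laboratory (46 features) or field (18
    time-domain HRV features).  PCA keeps the smallest number of components
    explaining ``pca_variance_retained`` of the training variance;
    ``regularization_strength`` is the inverse-regularization C of the L2
    logistic regression.
    """

    feature_set: str = "laboratory"
    pca_variance_retained: float = 0.95
    regularization_strength: float = 1.0
    max_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ConfigError(
                f"unknown feature_set {self.feature_set!r}; "
                f"expected one of {sorted(FEATURE_SETS)}"
            )
        if not 0.0 < self.pca_variance_retained <= 1.0:
            raise ConfigError("pca_variance_retained must be in (0, 1]")
        if self.regularization_strength <= 0:
            raise ConfigError("regularization_strength must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FittedPipeline:
    """A fold's fitted scaler -> PCA -> logistic-regression chain."""

    pipeline: Pipeline
    feature_names: list[str]
    n_components_retained: int
    config: ModelConfig

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict(features)


@dataclass(frozen=True)
class ClassificationReport:
    """Pooled per-class metrics over all LOSO folds."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    macro_f1: float
    feature_set: str
    n_features: int
    n_folds: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        """Render the per-class table (3-decimal rounding happens here,
        at report time only)."""
        lines = [
            f"feature_set: {self.feature_set} ({self.n_features} features, "
            f"{self.n_folds} LOSO folds)",
            f"{'':6s}{'precision':>10s}{'recall':>10s}{'f1-score':>10s}{'support':>10s}",
        ]
        for cls in CLASSES:
            lines.append(
                f"{cls:6s}{self.precision[cls]:>10.3f}{self.recall[cls]:>10.3f}"
                f"{self.f1[cls]:>10.3f}{self.support[cls]:>10d}"
            )
        lines.append(
            f"{'':6s}accuracy {self.accuracy:.3f}   macro-F1 {self.macro_f1:.3f}"
        )
        return "\n".join(lines)


@dataclass
class FoldResult:
    """Held-out material of one LOSO fold, kept for importance analysis."""

    test_subject: str
    fitted: FittedPipeline
    test_features: pd.DataFrame
    test_labels: np.ndarray
    predictions: np.ndarray


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2*p*r/(p+r); defined as 0 (with a warning) when both
    are zero."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        logger.warning("precision + recall == 0; F1 defined as 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def select_features(features: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Reduce a canonical 46-column feature frame to the configured set.

    ``field`` keeps exactly the 18 time-domain HRV columns; respiration
    statistics, although time-domain quantities, form their own family and
    are excluded from the field set.
    """
    if feature_set not in FEATURE_SETS:
        raise ConfigError(f"unknown feature_set {feature_set!r}")
    return features[FEATURE_SETS[feature_set]]


def loso_folds(subject_ids: np.ndarray) -> list[tuple[list[str], str]]:
    """Enumerate leave-one-subject-out folds: one (train_subjects,
    test_subject) per unique subject, in sorted order."""
    unique = sorted(map(str, np.unique(subject_ids)))
    if len(unique) < 2:
        raise InvalidDatasetError("LOSO needs >= 2 subjects")
    return [([s for s in unique if s != test], test) for test in unique]


def fit_fold(
    train_features: pd.DataFrame | np.ndarray,
    train_labels: np.ndarray,
    config: ModelConfig,
) -> FittedPipeline:
    """Fit scaler, PCA and logistic regression on one fold's training rows.

    Zero-variance features are scaled by 1 (scikit-learn's convention).
    With ``pca_variance_retained == 1.0`` all ``min(rows - 1, columns)``
    components are kept.
    """
    if isinstance(train_features, pd.DataFrame):
        names = list(train_features.columns)
        X = train_features.to_numpy(dtype=float)
    else:
        X = np.asarray(train_features, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if len(np.unique(train_labels)) < 2:
        raise InvalidDatasetError("training fold must contain both classes")
    if config.pca_variance_retained >= 1.0:
        n_components = min(X.shape[0] - 1, X.shape[1])
    else:
        n_components = config.pca_variance_retained
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=n_components, svd_solver="full",
                    random_state=config.seed)),
        ("logreg", LogisticRegression(  # default penalty: L2
            C=config.regularization_strength,
            solver="lbfgs",
            max_iter=config.max_iterations,
            random_state=config.seed,
        )),
    ])
    pipe.fit(X, train_labels)
    return FittedPipeline(
        pipeline=pipe,
        feature_names=names,
        n_components_retained=int(pipe.named_steps["pca"].n_components_),
        config=config,
    )


def run_loso(
    features: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    config: ModelConfig,
) -> list[FoldResult]:
    """Fit and predict every LOSO fold; rows whose active features contain
    NaN sentinels are dropped (logged) before folding."""
    X = select_features(features, config.feature_set)
    keep = ~X.isna().any(axis=1).to_numpy()
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        logger.warning(
            "dropped %d observation(s) with missing features for set %s",
            n_dropped, config.feature_set,
        )
    X = X.loc[keep].reset_index(drop=True)
    labels = np.asarray(labels)[keep]
    subjects = np.asarray(subjects)[keep]
    if len(np.unique(labels)) < 2:
        raise InvalidDatasetError("both classes must survive NaN filtering")

    results: list[FoldResult] = []
    for train_subjects, test_subject in loso_folds(subjects):
        train_mask = subjects != test_subject
        fitted = fit_fold(X.loc[train_mask], labels[train_mask], config)
        test_X = X.loc[~train_mask].reset_index(drop=True)
        test_y = labels[~train_mask]
        results.append(FoldResult(
            test_subject=test_subject,
            fitted=fitted,
            test_features=test_X,
            test_labels=test_y,
            predictions=fitted.predict(test_X),
        ))
    return results


def report_from_folds(
    folds: list[FoldResult], config: ModelConfig
) -> ClassificationReport:
    """Pool held-out predictions across folds and compute per-class
    precision/recall/F1/support plus overall accuracy and macro-F1."""
    y_true = np.concatenate([f.test_labels for f in folds])
    y_pred = np.concatenate([f.predictions for f in folds])
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CLASSES), zero_division=0.0
    )
    return ClassificationReport(
        precision=dict(zip(CLASSES, map(float, prec))),
        recall=dict(zip(CLASSES, map(float, rec))),
        f1=dict(zip(CLASSES, map(float, f1))),
        support=dict(zip(CLASSES, map(int, support))),
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_f1=float(np.mean(f1)),
        feature_set=config.feature_set,
        n_features=len(FEATURE_SETS[config.feature_set]),
        n_folds=len(folds),
    )


def evaluate_loso(
    features: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    config: ModelConfig,
) -> ClassificationReport:
    """Full LOSO evaluation: fold, fit, pool, report."""
    return report_from_folds(run_loso(features, labels, subjects, config), config)
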