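"""Permutation feature importance across leave-one-subject-out folds.

Importance of a feature is the drop in the fitted pipeline's held-out
score (macro-F1 by default) when that feature's column is shuffled within
the held-out rows, averaged over repeats.  Shuffling happens on the *raw*
input features, before scaling and PCA, so importance stays attributable
to named features despite the PCA mixing them.  Fold-wise importances are
aggregated into a distributional summary (median, quartiles, mean, SD,
outliers beyond 1.5 IQR) ranked by median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from .classify import FittedPipeline, FoldResult
from .errors import InvalidDatasetError, InvalidParameterError

logger = logging.getLogger(__name__)

SCORERS = {
    "macro_f1": lambda yt, yp: f1_score(yt, yp, average="macro", zero_division=0.0),
    "accuracy": accuracy_score,
}


@dataclass(frozen=True)
class ImportanceSummary:
    """Fold x feature importance values plus their ranked summary.

    ``values`` has one row per contributing fold and one column per
    feature; ``summary`` has columns median/q1/q3/mean/sd/n_folds/
    n_outliers, sorted by descending median (stable).
    """

    values: pd.DataFrame
    summary: pd.DataFrame

    @property
    def ranked_features(self) -> list[str]:
        return list(self.summary.index)


def permutation_importance(
    fitted: FittedPipeline,
    test_features: pd.DataFrame,
    test_labels: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
    scoring: str = "macro_f1",
) -> pd.Series:
    """Per-feature mean score drop on one held-out fold.

    Input data are never mutated; each repeat shuffles a copy of the
    feature's column with a seeded generator.
    """
    if n_repeats < 1:
        raise InvalidParameterError("n_repeats must be >= 1")
    if scoring not in SCORERS:
        raise InvalidParameterError(f"unknown scoring {scoring!r}")
    if len(np.unique(test_labels)) < 2:
        raise InvalidDatasetError("held-out fold must contain both classes")
    score = SCORERS[scoring]
    rng = np.random.default_rng(seed)
    X = test_features[fitted.feature_names].to_numpy(dtype=float)
    baseline = score(test_labels, fitted.pipeline.predict(X))
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            acc += baseline - score(test_labels, fitted.pipeline.predict(Xp))
        drops[j] = acc / n_repeats
    return pd.Series(drops, index=fitted.feature_names, name="importance")


def aggregate_importance(
    fold_results: list[pd.Series], feature_names: list[str] | None = None
) -> ImportanceSummary:
    """Aggregate per-fold importance series into a ranked summary.

    Outliers are values beyond 1.5 IQR outside the quartiles.  Features are
    ranked by median importance, descending, with a stable sort.
    """
    if len(fold_results) < 2:
        raise InvalidDatasetError("need >= 2 folds to summarise importance")
    values = pd.DataFrame(fold_results).reset_index(drop=True)
    if feature_names is not None:
        values = values[feature_names]
    q1 = values.quantile(0.25)
    q3 = values.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    n_outliers = ((values.lt(lo)) | (values.gt(hi))).sum()
    summary = pd.DataFrame({
        "median": values.median(),
        "q1": q1,
        "q3": q3,
        "mean": values.mean(),
        "sd": values.std(ddof=1),
        "n_folds": len(values),
        "n_outliers": n_outliers,
    })
    summary = summary.sort_values("median", ascending=False, kind="stable")
    return ImportanceSummary(values=values, summary=summary)


def loso_importance(
    folds: list[FoldResult],
    n_repeats: int = 10,
    seed: int = 0,
    scoring: str = "macro_f1",
) -> ImportanceSummary:
    """Permutation importance on every LOSO fold, aggregated.

    Folds whose held-out subject carries a single class cannot be scored
    and are skipped with a warning.
    """
    per_fold: list[pd.Series] = []
    for i, fold in enumerate(folds):
        if len(np.unique(fold.test_labels)) < 2:
            logger.warning(
                "fold %s has a single-class test set; skipped", fold.test_subject
            )
            continue
        per_fold.append(
            permutation_importance(
                fold.fitted, fold.test_features, fold.test_labels,
                n_repeats=n_repeats, seed=seed + i, scoring=scoring,
            )
        )
    return aggregate_importance(per_fold)


def plot_importance(summary: ImportanceSummary, path: str, top_n: int | None = None):
    """Box-plot of fold-wise importances per feature (most important at the
    top), written to ``path``.  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = summary.ranked_features
    if top_n is not None:
        order = order[:top_n]
    data = [summary.values[f].dropna().to_numpy() for f in order]
    fig, ax = plt.subplots(figsize=(8, max(4, 0.25 * len(order))))
    ax.boxplot(data[::-1], vert=False, tick_labels=order[::-1])
    ax.set_xlabel("permutation importance (score drop)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
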