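"""Baseline normalization: absolute feature differences between epoch pairs.

Inter-individual variability dominates raw HRV features, so each epoch is
re-expressed as its distance from the same subject's baseline: the
element-wise absolute difference between the feature vectors of an epoch
pair.  BL/BL pairs (both epochs baseline) carry the label ``BL`` —
"how much does a resting epoch differ from another resting epoch" — and
BL/CPT pairs carry ``CPT``.  Two strategies are provided:

* ``all_pairs`` (default): every unordered BL-BL pair and every (BL, CPT)
  pair of a subject becomes one observation.
* ``mean_baseline_reference``: each epoch is differenced against the
  subject's mean baseline feature vector, one observation per epoch.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InvalidDatasetError, InvalidParameterError
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

IDENTITY_COLUMNS = ["subject_id", "condition", "epoch_index"]
PAIR_COLUMNS = ["subject_id", "label", "pair_ref", "pair_other"]

STRATEGIES = ("all_pairs", "mean_baseline_reference")


def _epoch_key(row: pd.Series) -> str:
    return f"{row['condition']}{int(row['epoch_index'])}"


def build_pairs(
    vectors: pd.DataFrame, strategy: str = "all_pairs"
) -> pd.DataFrame:
    """Build baseline-normalized paired observations from a feature table.

    Parameters
    ----------
    vectors : DataFrame
        One row per epoch with the identity columns ``subject_id``,
        ``condition``, ``epoch_index`` and the 46 canonical feature columns.
    strategy : str
        ``all_pairs`` or ``mean_baseline_reference``.

    Returns
    -------
    DataFrame
        One row per paired observation: ``subject_id``, ``label`` (BL/CPT),
        ``pair_ref``/``pair_other`` epoch references and the 46 |delta|
        feature columns.  Subjects without any baseline epoch are excluded
        with a warning.  NaN feature sentinels propagate into the pair and
        are resolved at design-matrix time.
    """
    if strategy not in STRATEGIES:
        raise InvalidParameterError(
            f"unknown pairing strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    missing = [c for c in IDENTITY_COLUMNS + FEATURE_NAMES if c not in vectors]
    if missing:
        raise InvalidDatasetError(f"feature table missing columns: {missing[:5]}")

    rows: list[dict] = []
    for subject_id, sub in vectors.groupby("subject_id", sort=True):
        sub = sub.sort_values(["condition", "epoch_index"])
        bl = sub[sub["condition"] == "BL"]
        other = sub[sub["condition"] != "BL"]
        if bl.empty:
            logger.warning("subject %s has no BL epoch; excluded", subject_id)
            continue
        feats_bl = bl[FEATURE_NAMES].to_numpy(dtype=float)
        if strategy == "all_pairs":
            for i, j in combinations(range(len(bl)), 2):
                rows.append({
                    "subject_id": subject_id,
                    "label": "BL",
                    "pair_ref": _epoch_key(bl.iloc[i]),
                    "pair_other": _epoch_key(bl.iloc[j]),
                    **dict(zip(FEATURE_NAMES, np.abs(feats_bl[i] - feats_bl[j]))),
                })
            feats_o = other[FEATURE_NAMES].to_numpy(dtype=float)
            for i in range(len(bl)):
                for j in range(len(other)):
                    rows.append({
                        "subject_id": subject_id,
                        "label": str(other.iloc[j]["condition"]),
                        "pair_ref": _epoch_key(bl.iloc[i]),
                        "pair_other": _epoch_key(other.iloc[j]),
                        **dict(zip(FEATURE_NAMES, np.abs(feats_bl[i] - feats_o[j]))),
                    })
        else:  # mean_baseline_reference
            ref = np.nanmean(feats_bl, axis=0)
            for _, row in sub.iterrows():
                feats = row[FEATURE_NAMES].to_numpy(dtype=float)
                rows.append({
                    "subject_id": subject_id,
                    "label": str(row["condition"]),
                    "pair_ref": "BLmean",
                    "pair_other": _epoch_key(row),
                    **dict(zip(FEATURE_NAMES, np.abs(feats - ref))),
                })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS + FEATURE_NAMES)


def assemble_design_matrix(
    observations: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Split a paired-observation table into model inputs.

    Returns ``(features, labels, subject_ids)`` with features a DataFrame
    in canonical column order and rows ordered by (subject, pair).  Raises
    :class:`InvalidDatasetError` when the table is empty, has fewer than
    two subjects, or contains a single class.
    """
    if observations.empty:
        raise InvalidDatasetError("no paired observations")
    obs = observations.sort_values(
        ["subject_id", "pair_ref", "pair_other"], kind="stable"
    ).reset_index(drop=True)
    labels = obs["label"].to_numpy()
    subjects = obs["subject_id"].to_numpy()
    if len(np.unique(subjects)) < 2:
        raise InvalidDatasetError("need >= 2 subjects")
    if len(np.unique(labels)) < 2:
        raise InvalidDatasetError("both classes (BL, CPT) must be present")
    return obs[FEATURE_NAMES].copy(), labels, subjects
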