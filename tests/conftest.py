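import numpy as np
import pandas as pd
import pytest

import painhrv as ph


def make_epoch(intervals, subject_id="s1", condition="BL", epoch_index=0,
               start_time=0.0):
    """Build an Epoch directly from an interval list (ms)."""
    intervals = np.asarray(intervals, dtype=float)
    beat_times = start_time + np.cumsum(intervals)
    return ph.Epoch(
        subject_id=subject_id,
        condition=condition,
        epoch_index=epoch_index,
        start_time=start_time,
        intervals=intervals,
        beat_times=beat_times,
    )


def featurize_cohort(cohort) -> pd.DataFrame:
    """Epoch and featurize every segment of a cohort into a feature table."""
    rows = []
    for subject in cohort.subjects:
        for _, series in subject.segments:
            for epoch in ph.segment_epochs(series):
                v = ph.assemble_feature_vector(epoch)
                rows.append({
                    "subject_id": v.subject_id,
                    "condition": v.condition,
                    "epoch_index": v.epoch_index,
                    **v.values,
                })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, full-length segments, strong pain effect: enough for
    pairing/classification tests without the cost of the full cohort."""
    config = ph.SimulationConfig(
        n_subjects=6, dropout_fraction=0.0, seed=123,
        pain_hr_delta_mean=15.0, pain_hr_delta_sd=4.0,
        pain_rsa_scale=0.5, noise_sd_ms=20.0,
    )
    return ph.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort) -> pd.DataFrame:
    return featurize_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_dataset(small_feature_table):
    pairs = ph.build_pairs(small_feature_table, strategy="all_pairs")
    return ph.assemble_design_matrix(pairs)
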