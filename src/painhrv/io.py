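"""File round-tripping: beat tables, feature tables, reports, configs.

Everything is plain delimited text or YAML/JSON so outputs diff cleanly
and reruns with the same seed are byte-identical.  Each writer prepends a
``#``-commented provenance header (config hash and seed) which pandas
readers skip transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, SimulationConfig
from .errors import ConfigError, InvalidDatasetError
from .features import FEATURE_NAMES, FeatureVector
from .ingest import ECGTrace, RRISeries
from .pairing import PAIR_COLUMNS

BEAT_COLUMNS = ["subject_id", "condition", "beat_time_ms", "rri_ms"]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance_line(config: dict | None, seed: int | None) -> str:
    parts = ["# painhrv"]
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def _write_csv(df: pd.DataFrame, path: Path, config: dict | None, seed: int | None):
    with open(path, "w") as fh:
        fh.write(_provenance_line(config, seed) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_cohort(cohort: CohortDataset, beat_path: str | Path,
                 config_path: str | Path | None = None) -> None:
    """Write a cohort as one row per beat (subject_id, condition,
    beat_time_ms, rri_ms); the simulation config is echoed to YAML
    alongside when ``config_path`` is given."""
    rows = []
    for subject in cohort.subjects:
        for condition, series in subject.segments:
            for bt, iv in zip(series.beat_times[1:], series.intervals):
                rows.append((subject.subject_id, condition, bt, iv))
    df = pd.DataFrame(rows, columns=BEAT_COLUMNS)
    cfg = cohort.config.to_dict()
    _write_csv(df, Path(beat_path), cfg, cohort.config.seed)
    if config_path is not None:
        with open(config_path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def read_beat_table(path: str | Path) -> list[RRISeries]:
    """Read a beat table back into per-subject, per-condition RRI series."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidDatasetError(f"beat table missing columns {missing}")
    if df.empty:
        raise InvalidDatasetError("beat table is empty")
    out: list[RRISeries] = []
    for (subject_id, condition), grp in df.groupby(
        ["subject_id", "condition"], sort=True
    ):
        grp = grp.sort_values("beat_time_ms")
        term = grp["beat_time_ms"].to_numpy(dtype=float)
        iv = grp["rri_ms"].to_numpy(dtype=float)
        first = term[0] - iv[0]
        out.append(RRISeries(
            subject_id=str(subject_id),
            condition=str(condition),
            beat_times=np.concatenate([[first], term]),
            intervals=iv,
        ))
    return out


def read_ecg(path: str | Path, fs: float, subject_id: str = "",
             condition: str = "BL") -> ECGTrace:
    """Read a two-column delimited ECG file (time_s, amplitude_mV); the
    sampling rate comes from the caller (header/sidecar config)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise InvalidDatasetError("ECG file needs columns (time_s, amplitude_mV)")
    return ECGTrace(fs=fs, samples=df.iloc[:, 1].to_numpy(dtype=float),
                    subject_id=subject_id, condition=condition)


def write_feature_table(vectors: list[FeatureVector], path: str | Path,
                        config: dict | None = None, seed: int | None = None):
    """One row per epoch: identity columns then the 46 canonical features."""
    rows = [
        {"subject_id": v.subject_id, "condition": v.condition,
         "epoch_index": v.epoch_index, **v.values}
        for v in vectors
    ]
    df = pd.DataFrame(
        rows, columns=["subject_id", "condition", "epoch_index"] + FEATURE_NAMES
    )
    _write_csv(df, Path(path), config, seed)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise InvalidDatasetError(
            f"feature table missing {len(missing)} columns (e.g. {missing[:3]})"
        )
    return df


def write_pair_table(pairs: pd.DataFrame, path: str | Path,
                     config: dict | None = None, seed: int | None = None):
    _write_csv(pairs[PAIR_COLUMNS + FEATURE_NAMES], Path(path), config, seed)


def write_report(report, path: str | Path, config: dict | None = None):
    payload = {"report": report.to_dict()}
    if config is not None:
        payload["provenance"] = {"config": config, "config_hash": config_hash(config)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_run_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a YAML run config, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def simulation_config_from_file(path: str | Path) -> SimulationConfig:
    allowed = set(SimulationConfig().to_dict())
    return SimulationConfig(**load_run_config(path, allowed))
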