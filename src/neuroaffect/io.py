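"""Reading and writing of cohorts, recordings, configs, and result reports.

All on-disk formats are plain text: UTF-8 CSV with a header row and "."
decimal for tabular data (full-precision floats, so scientific-notation
band-power values round-trip exactly), YAML for configurations, and JSON
for result reports.  Raw recordings are stored as one CSV column per
channel with an implicit sample index, plus a JSON sidecar carrying the
sampling rate, channel labels and condition tag.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .eeg import EEGRecording
from .exceptions import InputError
from .synthetic import Cohort, GenerativeConfig

__all__ = [
    "REQUIRED_COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_recording",
    "write_recording",
    "read_generative_config",
    "write_generative_config",
    "write_json",
    "to_jsonable",
    "config_hash",
]

REQUIRED_COHORT_COLUMNS = (
    "participant_id", "pa_pre", "na_pre", "pa_post", "na_post",
    "theta_change", "gamma_change", "affective_shift",
    "delta_positive", "delta_negative",
)


def write_cohort(cohort: Union[Cohort, pd.DataFrame], path) -> Path:
    """Write a cohort table as UTF-8 CSV, one participant per row."""
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    path = Path(path)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending column/row."""
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"cohort file {path} is missing columns: {missing}")
    numeric = [c for c in REQUIRED_COHORT_COLUMNS if c != "participant_id"]
    for col in numeric:
        bad = frame.index[~np.isfinite(frame[col].to_numpy(dtype=float))]
        if len(bad):
            raise InputError(
                f"cohort file {path}: non-finite value in column {col!r}, "
                f"row {int(bad[0])}")
    return frame


def write_recording(recording: EEGRecording, path) -> Path:
    """Write a recording as channel-per-column CSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(recording.samples.T,
                 columns=recording.channel_labels).to_csv(path, index=False)
    sidecar = {"fs": recording.fs, "labels": list(recording.channel_labels),
               "condition": recording.condition}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8")
    return path


def read_recording(path) -> EEGRecording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise InputError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    frame = pd.read_csv(path)
    if list(frame.columns) != list(meta["labels"]):
        raise InputError(f"channel labels in {path} disagree with sidecar")
    return EEGRecording(channel_labels=list(meta["labels"]), fs=float(meta["fs"]),
                        samples=frame.to_numpy(dtype=float).T,
                        condition=meta.get("condition", "pre"))


def write_generative_config(config: GenerativeConfig, path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(config)
    payload["coef_positive"] = list(payload["coef_positive"])
    payload["coef_negative"] = list(payload["coef_negative"])
    path.write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
    return path


def read_generative_config(path) -> GenerativeConfig:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    payload["coef_positive"] = tuple(payload["coef_positive"])
    payload["coef_negative"] = tuple(payload["coef_negative"])
    config = GenerativeConfig(**payload)
    config.validate()
    return config


def to_jsonable(obj):
    """Recursively convert dataclasses / numpy / pandas objects for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return {str(idx): {k: to_jsonable(v) for k, v in row.items()}
                for idx, row in obj.to_dict(orient="index").items()}
    if isinstance(obj, pd.Series):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(to_jsonable(obj), indent=1), encoding="utf-8")
    tmp.replace(path)  # atomic on POSIX
    return path


def config_hash(config) -> str:
    """Stable SHA-256 over the canonical JSON form of a configuration."""
    blob = json.dumps(to_jsonable(config), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]
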