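"""On-disk formats: HDF5 signal containers, CSV tables, JSON sidecars.

Every reader validates the artifact's schema and fails loudly on a
corrupted or mismatched file.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import AcquisitionRecord, GroundTruth, SubjectRecord, stratum_of

__all__ = [
    "save_record", "load_record", "cohort_to_csv", "cohort_from_csv",
    "save_features", "load_features", "COHORT_COLUMNS",
]

COHORT_COLUMNS = ("subject_id", "age", "gender", "bmi", "ef", "lvedp",
                  "stratum", "cad_obstructive", "site_id")


def save_record(record: AcquisitionRecord, path) -> None:
    """Write /ovg, /ppg and sampling attributes; ground truth (when
    present) goes to a JSON sidecar next to the container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("ovg", data=record.ovg, dtype="float64")
        f.create_dataset("ppg", data=record.ppg, dtype="float64")
        f.attrs["ovg_rate"] = record.ovg_rate
        f.attrs["ppg_rate"] = record.ppg_rate
        f.attrs["duration"] = record.duration
        f.attrs["subject_id"] = record.subject_id
    if record.truth is not None:
        t = record.truth
        sidecar = {
            "beat_onsets": np.asarray(t.beat_onsets).tolist(),
            "atrial_durations": np.asarray(t.atrial_durations).tolist(),
            "pulse_base_values": np.asarray(t.pulse_base_values).tolist(),
            "injected_noise": [[k, v] for k, v in t.injected_noise],
            "effect_params": t.effect_params,
            "ovg_ppg_delay": t.ovg_ppg_delay,
        }
        path.with_suffix(".truth.json").write_text(json.dumps(sidecar))


def load_record(path) -> AcquisitionRecord:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if "ovg" not in f or "ppg" not in f:
                raise SchemaError(f"{path}: missing /ovg or /ppg dataset")
            ovg = f["ovg"][()]
            ppg = f["ppg"][()]
            attrs = dict(f.attrs)
    except OSError as exc:
        raise SchemaError(f"{path}: not a readable signal container ({exc})") from exc
    for key in ("ovg_rate", "ppg_rate", "duration"):
        if key not in attrs:
            raise SchemaError(f"{path}: missing attribute {key!r}")
    if ovg.ndim != 2 or ovg.shape[0] != 3 or ppg.ndim != 2 or ppg.shape[0] != 2:
        raise SchemaError(f"{path}: wrong dataset shapes {ovg.shape}, {ppg.shape}")
    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        truth = GroundTruth(
            beat_onsets=np.asarray(d["beat_onsets"]),
            atrial_durations=np.asarray(d["atrial_durations"]),
            pulse_base_values=np.asarray(d["pulse_base_values"]),
            injected_noise=[tuple(x) for x in d["injected_noise"]],
            effect_params=d["effect_params"],
            ovg_ppg_delay=d.get("ovg_ppg_delay", 0.0))
    return AcquisitionRecord(
        ovg=ovg, ppg=ppg, ovg_rate=float(attrs["ovg_rate"]),
        ppg_rate=float(attrs["ppg_rate"]), duration=float(attrs["duration"]),
        subject_id=str(attrs.get("subject_id", "")), truth=truth)


def cohort_to_csv(subjects: list[SubjectRecord], path) -> None:
    df = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "gender": s.gender,
        "bmi": s.bmi, "ef": s.ef, "lvedp": s.lvedp, "stratum": s.stratum,
        "cad_obstructive": s.cad_obstructive, "site_id": s.site_id,
    } for s in subjects])
    df.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing cohort columns {sorted(missing)}")
    if (df["lvedp"] < 0).any() or (df["lvedp"] > 45).any():
        raise SchemaError(f"{path}: lvedp outside [0, 45] mmHg")
    bad = df[df.apply(lambda r: stratum_of(r["lvedp"]) != r["stratum"], axis=1)]
    if not bad.empty:
        raise SchemaError(f"{path}: stratum inconsistent with lvedp for "
                          f"{bad['subject_id'].tolist()[:5]}")
    return df.set_index("subject_id")


def save_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=True)


def load_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.empty or df.columns.size == 0:
        raise SchemaError(f"{path}: empty feature table")
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric feature columns {non_numeric}")
    return df
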