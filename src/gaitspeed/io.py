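"""Data model and on-disk formats.

All artifacts are plain CSV with JSON sidecars. A recording is a CSV with
columns ``time_s, ax_g, ay_g, az_g`` plus a companion ``<stem>.meta.json``
holding ``{subject_id, location, side, fs_hz}``. Annotations, subject
metadata, feature tables, predictions and reports use the documented CSV /
JSON schemas below. Readers validate the type invariants and refuse to
coerce malformed input silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOCATIONS = ("sacrum", "thigh", "shank")
SIDES = ("left", "right", "midline")
TEST_TYPES = ("treadmill_walk", "sixMWT", "PCT")
COHORTS = ("healthy", "MS")


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


@dataclass
class AccelRecording:
    """One device's timestamped tri-axial acceleration series, in G.

    ``t`` is seconds from recording start and must be strictly increasing;
    the Z axis points roughly anterior (thigh, shank) or posterior (sacrum),
    so yaw about Z is the only unconstrained part of the mounting.
    """

    subject_id: str
    location: str
    side: str
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown location {self.location!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.location == "sacrum" and self.side != "midline":
            raise ValidationError("sacrum recordings must have side='midline'")
        if self.location != "sacrum" and self.side == "midline":
            raise ValidationError(f"{self.location} recordings need side left/right")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValidationError(
                f"axis lengths {len(self.ax)},{len(self.ay)},{len(self.az)} "
                f"do not match {n} timestamps"
            )
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                f"timestamps not strictly increasing at index {int(bad[0]) + 1} "
                f"(t={self.t[bad[0] + 1]!r})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass(frozen=True)
class TestAnnotation:
    """One annotated test interval with its ground-truth treadmill speed.

    PCT (quiet standing) tests carry truth_speed 0 by protocol.
    """

    subject_id: str
    test_id: str
    test_type: str
    t_start: float
    t_end: float
    truth_speed: float

    def __post_init__(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise ValidationError(f"unknown test_type {self.test_type!r}")
        if not self.t_end > self.t_start:
            raise ValidationError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        if self.truth_speed < 0:
            raise ValidationError(f"truth_speed must be >= 0, got {self.truth_speed}")
        if self.test_type == "PCT" and self.truth_speed != 0.0:
            raise ValidationError(
                f"PCT implies truth_speed 0, got {self.truth_speed}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject cohort and clinical metadata.

    Optional fields are None when not collected. ``t25fw_speed`` is the
    comfortable walking speed from the Timed 25 Foot Walk, used to assign
    MS subjects to impairment groups.
    """

    subject_id: str
    cohort: str
    edss_sr: float | None = None
    msws: float | None = None
    fell_last_6mo: bool | None = None
    t25fw_speed: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.edss_sr is not None and not 0 <= self.edss_sr <= 10:
            raise ValidationError(f"EDSS_SR out of range [0, 10]: {self.edss_sr}")
        if self.msws is not None and not 0 <= self.msws <= 1:
            raise ValidationError(f"MSWS out of range [0, 1]: {self.msws}")
        if self.t25fw_speed is not None and self.t25fw_speed < 0:
            raise ValidationError(f"negative t25fw_speed: {self.t25fw_speed}")


N_FEATURES = 32
FEATURE_COLUMNS = [f"f{i:02d}" for i in range(1, N_FEATURES + 1)]
FEATURE_TABLE_COLUMNS = (
    ["subject_id", "test_id", "window_index", "location"]
    + FEATURE_COLUMNS
    + ["truth_speed_mps"]
)


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the feature-table invariants; return the validated frame.

    Exactly 32 features per row, window_index unique within
    (subject, test, location), all feature values finite.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    extra_f = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()
               and c not in FEATURE_COLUMNS]
    if extra_f:
        raise FormatError(
            f"feature table has {len(FEATURE_COLUMNS) + len(extra_f)} feature "
            f"columns; exactly {N_FEATURES} are expected"
        )
    if (df["window_index"] < 0).any():
        row = int(df.index[df["window_index"] < 0][0])
        raise ValidationError(f"negative window_index at row {row}")
    dup = df.duplicated(subset=["subject_id", "test_id", "location", "window_index"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValidationError(f"duplicate (subject, test, location, window) at row {row}")
    feats = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(feats).all():
        bad = np.argwhere(~np.isfinite(feats))[0]
        raise ValidationError(
            f"non-finite feature {FEATURE_COLUMNS[bad[1]]} at row {int(bad[0])}"
        )
    return df


# ---------------------------------------------------------------------------
# recordings

def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(rec: AccelRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus a ``<stem>.meta.json`` sidecar.

    Timestamps are stored relative to recording start; the start epoch
    (``t0_s`` on the session clock) lives in the sidecar so multi-device
    alignment survives the round trip.
    """
    path = Path(path)
    t0 = float(rec.t[0]) if len(rec.t) else 0.0
    df = pd.DataFrame({"time_s": rec.t - t0, "ax_g": rec.ax, "ay_g": rec.ay,
                       "az_g": rec.az})
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "subject_id": rec.subject_id,
        "location": rec.location,
        "side": rec.side,
        "fs_hz": rec.fs,
        "t0_s": t0,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> AccelRecording:
    """Read a recording CSV with its JSON sidecar.

    Timestamps are re-referenced to seconds from recording start, then
    shifted by the sidecar's ``t0_s`` session epoch when present. The
    sampling rate comes from the sidecar when present, otherwise it is
    inferred from the median timestamp increment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "ax_g", "ay_g", "az_g"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    meta: dict = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise FormatError(f"{path}: empty recording")
    t = t - t[0] + float(meta.get("t0_s", 0.0))
    fs = meta.get("fs_hz")
    if fs is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    return AccelRecording(
        subject_id=str(meta.get("subject_id", path.stem)),
        location=meta.get("location", "sacrum"),
        side=meta.get("side", "midline"),
        fs=float(fs),
        t=t,
        ax=df["ax_g"].to_numpy(dtype=float),
        ay=df["ay_g"].to_numpy(dtype=float),
        az=df["az_g"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# annotations and subjects

_ANN_COLUMNS = ["subject_id", "test_id", "test_type", "t_start_s", "t_end_s",
                "truth_speed_mps"]


def write_annotations(anns: Iterable[TestAnnotation], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": a.subject_id, "test_id": a.test_id,
            "test_type": a.test_type, "t_start_s": a.t_start,
            "t_end_s": a.t_end, "truth_speed_mps": a.truth_speed,
        }
        for a in anns
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, index=False, float_format="%.9g")
    return path


def read_annotations(path: str | Path) -> list[TestAnnotation]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(TestAnnotation(
                subject_id=str(row["subject_id"]),
                test_id=str(row["test_id"]),
                test_type=str(row["test_type"]),
                t_start=float(row["t_start_s"]),
                t_end=float(row["t_end_s"]),
                truth_speed=float(row["truth_speed_mps"]),
            ))
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    return out


_SUBJ_COLUMNS = ["subject_id", "cohort", "edss_sr", "msws", "fell_last_6mo",
                 "t25fw_speed_mps"]


def write_subjects(subjects: Iterable[SubjectRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id, "cohort": s.cohort,
            "edss_sr": "" if s.edss_sr is None else s.edss_sr,
            "msws": "" if s.msws is None else s.msws,
            "fell_last_6mo": "" if s.fell_last_6mo is None else str(s.fell_last_6mo),
            "t25fw_speed_mps": "" if s.t25fw_speed is None else s.t25fw_speed,
        })
    pd.DataFrame(rows, columns=_SUBJ_COLUMNS).to_csv(path, index=False, float_format="%.9g")
    return path


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot parse boolean {v!r}")


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _SUBJ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SubjectRecord(
                subject_id=str(row["subject_id"]),
                cohort=str(row["cohort"]),
                edss_sr=_opt_float(row["edss_sr"]),
                msws=_opt_float(row["msws"]),
                fell_last_6mo=_opt_bool(row["fell_last_6mo"]),
                t25fw_speed=_opt_float(row["t25fw_speed_mps"]),
            ))
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# feature tables, predictions, reports

def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    validate_feature_table(df)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    return validate_feature_table(df)


def import_external_feature_table(
    path: str | Path,
    column_map: Mapping[str, str],
    location: str | None = None,
) -> pd.DataFrame:
    """Import a third-party per-window feature file via a column mapping.

    ``column_map`` maps canonical names (``subject_id``, ``test_id``,
    ``window_index``, ``location``, ``truth_speed_mps``, ``f01``..``f32``)
    to the columns of the external CSV. Identifier columns missing from the
    map are synthesized (row order for ``window_index``); ``location`` may
    instead be supplied as a constant. Unknown external columns are ignored.
    """
    df = pd.read_csv(Path(path))
    out = pd.DataFrame()
    for canon, ext in column_map.items():
        if ext not in df.columns:
            raise FormatError(f"{path}: mapped column {ext!r} (for {canon}) not found")
        out[canon] = df[ext]
    missing_feats = [c for c in FEATURE_COLUMNS if c not in out.columns]
    if missing_feats:
        raise FormatError(
            f"column map covers {N_FEATURES - len(missing_feats)} of "
            f"{N_FEATURES} features; missing {missing_feats[:4]}..."
        )
    if "location" not in out.columns:
        if location is None:
            raise FormatError("no location column mapped and no constant given")
        out["location"] = location
    if "subject_id" not in out.columns:
        out["subject_id"] = "external"
    if "test_id" not in out.columns:
        out["test_id"] = "T1"
    if "window_index" not in out.columns:
        out["window_index"] = (
            out.groupby(["subject_id", "test_id", "location"]).cumcount()
        )
    if "truth_speed_mps" not in out.columns:
        raise FormatError("column map must cover truth_speed_mps")
    return validate_feature_table(out[FEATURE_TABLE_COLUMNS])


def write_predictions(preds, path: str | Path) -> Path:
    """Write test-level predictions (see :class:`gaitspeed.model.TestPrediction`)."""
    path = Path(path)
    rows = [
        {
            "subject_id": p.subject_id, "test_id": p.test_id,
            "median_estimate_mps": p.median_estimate, "truth_mps": p.truth,
            "n_windows": len(p.window_estimates),
        }
        for p in preds
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    return path


def write_report(report: Mapping, path: str | Path) -> Path:
    """Write an evaluation report as indented JSON."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=1, default=_default))
    return path
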