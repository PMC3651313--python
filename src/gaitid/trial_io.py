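"""Reading and writing of walking trials, feature tables and trained models.

A *trial* is a set of synchronized inertial-sensor recordings (3D specific
force and 3D angular velocity per sensor) together with the sampling
frequency, a static standing interval, the declared sensor configuration and,
optionally, ground-truth segment labels.  The on-disk interchange format is
deliberately plain: one CSV per sensor (columns ``time, ax, ay, az, gx, gy,
gz``) plus a JSON manifest.  Internal units are fixed to m/s² and rad/s;
conversion happens only at this boundary.

Feature tables can be exported as CSV or as ARFF (the Weka interchange
dialect: ``@relation`` / ``@attribute`` / ``@data``).  Trained identification
models are stored as JSON with the decision trees as nested node objects, so
a model file stays human-auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEGMENT_CLASSES",
    "MIDLINE_CLASSES",
    "SegmentLabel",
    "ConfigurationSpec",
    "full_body",
    "lower_trunk",
    "get_configuration",
    "SensorRecording",
    "Trial",
    "FeatureTable",
    "read_trial",
    "write_trial",
    "read_feature_table",
    "write_feature_table",
    "serialize_model",
    "load_model",
]

#: Segment classes distinguished in step 1 (no left/right).
SEGMENT_CLASSES = (
    "pelvis",
    "sternum",
    "head",
    "shoulder",
    "upper_arm",
    "forearm",
    "hand",
    "upper_leg",
    "lower_leg",
    "foot",
)

#: Classes on the body midline, which carry no side.
MIDLINE_CLASSES = frozenset({"pelvis", "sternum", "head"})

MODEL_SCHEMA_VERSION = 1

_ACC_UNITS = {"m/s^2": 1.0, "m/s2": 1.0, "g": 9.81}
_GYR_UNITS = {"rad/s": 1.0, "deg/s": np.pi / 180.0}


@dataclass(frozen=True, order=True)
class SegmentLabel:
    """A body segment: a segment class plus a side (``none`` on the midline)."""

    segment_class: str
    side: str = "none"

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.segment_class!r}")
        if self.side not in ("left", "right", "none"):
            raise ValueError(f"unknown side {self.side!r}")
        if (self.segment_class in MIDLINE_CLASSES) != (self.side == "none"):
            raise ValueError(
                f"segment {self.segment_class!r} cannot have side {self.side!r}"
            )

    def __str__(self) -> str:
        if self.side == "none":
            return self.segment_class
        return f"{self.side}_{self.segment_class}"

    @classmethod
    def parse(cls, text: str) -> "SegmentLabel":
        text = text.strip()
        for side in ("left", "right"):
            if text.startswith(side + "_"):
                return cls(text[len(side) + 1 :], side)
        return cls(text)


@dataclass(frozen=True)
class ConfigurationSpec:
    """The declared sensor set: an ordered collection of body segments."""

    name: str
    segments: tuple[SegmentLabel, ...]

    @property
    def n_sensors(self) -> int:
        return len(self.segments)

    @property
    def segment_classes(self) -> tuple[str, ...]:
        """Segment classes present, in first-appearance order."""
        seen: list[str] = []
        for seg in self.segments:
            if seg.segment_class not in seen:
                seen.append(seg.segment_class)
        return tuple(seen)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seg in self.segments:
            counts[seg.segment_class] = counts.get(seg.segment_class, 0) + 1
        return counts

    def __post_init__(self) -> None:
        if len(set(self.segments)) != len(self.segments):
            raise ValueError("duplicate segments in configuration")


def _sided(cls: str) -> tuple[SegmentLabel, SegmentLabel]:
    return SegmentLabel(cls, "right"), SegmentLabel(cls, "left")


def full_body() -> ConfigurationSpec:
    """The 17-sensor whole-body configuration."""
    segments: list[SegmentLabel] = [
        SegmentLabel("pelvis"),
        SegmentLabel("sternum"),
        SegmentLabel("head"),
    ]
    for cls in ("shoulder", "upper_arm", "forearm", "hand",
                "upper_leg", "lower_leg", "foot"):
        segments.extend(_sided(cls))
    return ConfigurationSpec("full_body", tuple(segments))


def lower_trunk() -> ConfigurationSpec:
    """The 8-sensor lower-body-plus-trunk configuration."""
    segments: list[SegmentLabel] = [SegmentLabel("pelvis"), SegmentLabel("sternum")]
    for cls in ("upper_leg", "lower_leg", "foot"):
        segments.extend(_sided(cls))
    return ConfigurationSpec("lower_trunk", tuple(segments))


def get_configuration(name: str,
                      segments: Sequence[str] | None = None) -> ConfigurationSpec:
    if name == "full_body":
        return full_body()
    if name == "lower_trunk":
        return lower_trunk()
    if name == "custom":
        if not segments:
            raise ValueError("custom configuration requires an explicit segment list")
        return ConfigurationSpec(
            "custom", tuple(SegmentLabel.parse(s) for s in segments)
        )
    raise ValueError(f"unknown configuration {name!r}")


@dataclass
class SensorRecording:
    """Raw signals of one sensor, in sensor coordinates (m/s², rad/s)."""

    sensor_id: str
    acc: np.ndarray  # (n, 3) specific force
    gyr: np.ndarray  # (n, 3) angular velocity

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"sensor {self.sensor_id}: acc must be (n, 3)")
        if self.gyr.shape != self.acc.shape:
            raise ValueError(
                f"sensor {self.sensor_id}: acc and gyr shapes differ "
                f"({self.acc.shape} vs {self.gyr.shape})"
            )
        if len(self.acc) < 2:
            raise ValueError(f"sensor {self.sensor_id}: needs at least 2 samples")
        for name, arr in (("acc", self.acc), ("gyr", self.gyr)):
            bad = ~np.isfinite(arr)
            if bad.any():
                idx = int(np.argwhere(bad)[0, 0])
                raise ValueError(
                    f"sensor {self.sensor_id}: non-finite {name} sample at index {idx}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.acc)


@dataclass
class Trial:
    """A validated set of synchronized sensor recordings."""

    sensors: list[SensorRecording]
    fs: float
    static_interval: tuple[int, int]
    config: ConfigurationSpec
    labels: dict[str, SegmentLabel] | None = None
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not self.sensors:
            raise ValueError("trial has no sensors")
        n = self.sensors[0].n_samples
        for rec in self.sensors:
            if rec.n_samples != n:
                raise ValueError(
                    f"ragged trial: sensor {rec.sensor_id} has {rec.n_samples} "
                    f"samples, expected {n}"
                )
        s, e = self.static_interval
        if not (0 <= s < e <= n):
            raise ValueError(f"static interval [{s}, {e}) outside [0, {n})")
        if len(self.sensors) != self.config.n_sensors:
            raise ValueError(
                f"trial has {len(self.sensors)} sensors but configuration "
                f"{self.config.name!r} declares {self.config.n_sensors}"
            )
        ids = [rec.sensor_id for rec in self.sensors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sensor ids")
        if self.labels is not None:
            if set(self.labels) != set(ids):
                raise ValueError("labels must cover exactly the trial's sensor ids")
            if sorted(self.labels.values()) != sorted(self.config.segments):
                raise ValueError(
                    "labels are not a bijection onto the configuration's segments"
                )

    @property
    def n_samples(self) -> int:
        return self.sensors[0].n_samples

    def sensor(self, sensor_id: str) -> SensorRecording:
        for rec in self.sensors:
            if rec.sensor_id == sensor_id:
                return rec
        raise KeyError(sensor_id)


@dataclass
class FeatureTable:
    """Per-sensor feature vectors, one row per sensor per trial.

    ``values`` is indexed by ``(trial_id, sensor_id)``; ``labels`` (optional)
    is aligned to the same index and holds segment-class strings or full
    segment labels depending on the pipeline step.
    """

    values: pd.DataFrame
    transform: str = "raw"
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("empty feature table")
        if self.transform not in ("raw", "rank", "normalize"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.labels is not None and not self.labels.index.equals(self.values.index):
            raise ValueError("labels index does not match values index")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Trial I/O
# ---------------------------------------------------------------------------

def write_trial(trial: Trial, directory: str | Path) -> Path:
    """Write ``trial`` as per-sensor CSVs plus ``manifest.json``; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.fs
    sensors_meta = []
    for rec in trial.sensors:
        fname = f"{rec.sensor_id}.csv"
        df = pd.DataFrame(
            np.column_stack([t, rec.acc, rec.gyr]),
            columns=["time", "ax", "ay", "az", "gx", "gy", "gz"],
        )
        df.to_csv(directory / fname, index=False, float_format="%.17g")
        meta: dict = {"id": rec.sensor_id, "file": fname}
        if trial.labels is not None:
            meta["label"] = str(trial.labels[rec.sensor_id])
        sensors_meta.append(meta)
    manifest = {
        "trial_id": trial.trial_id,
        "fs": trial.fs,
        "static_interval": list(trial.static_interval),
        "units": {"acc": "m/s^2", "gyr": "rad/s"},
        "configuration": {
            "name": trial.config.name,
            "segments": [str(s) for s in trial.config.segments],
        },
        "sensors": sensors_meta,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_trial(manifest_path: str | Path) -> Trial:
    """Read a trial from a JSON manifest referencing per-sensor CSV files."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    units = manifest.get("units", {})
    acc_unit = units.get("acc", "m/s^2")
    gyr_unit = units.get("gyr", "rad/s")
    if acc_unit not in _ACC_UNITS:
        raise ValueError(f"unknown acceleration unit {acc_unit!r}")
    if gyr_unit not in _GYR_UNITS:
        raise ValueError(f"unknown angular-velocity unit {gyr_unit!r}")
    acc_scale, gyr_scale = _ACC_UNITS[acc_unit], _GYR_UNITS[gyr_unit]

    cfg_meta = manifest["configuration"]
    config = get_configuration(cfg_meta["name"], cfg_meta.get("segments"))

    sensors: list[SensorRecording] = []
    labels: dict[str, SegmentLabel] = {}
    for meta in manifest["sensors"]:
        fpath = manifest_path.parent / meta["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"sensor {meta['id']}: data file missing: {fpath}"
            )
        df = pd.read_csv(fpath)
        missing = {"ax", "ay", "az", "gx", "gy", "gz"} - set(df.columns)
        if missing:
            raise ValueError(f"sensor {meta['id']}: missing columns {sorted(missing)}")
        sensors.append(
            SensorRecording(
                meta["id"],
                df[["ax", "ay", "az"]].to_numpy() * acc_scale,
                df[["gx", "gy", "gz"]].to_numpy() * gyr_scale,
            )
        )
        if "label" in meta:
            labels[meta["id"]] = SegmentLabel.parse(meta["label"])

    return Trial(
        sensors=sensors,
        fs=float(manifest["fs"]),
        static_interval=tuple(manifest["static_interval"]),
        config=config,
        labels=labels or None,
        trial_id=manifest.get("trial_id", manifest_path.parent.name),
    )


# ---------------------------------------------------------------------------
# Feature-table I/O (CSV and Weka ARFF)
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path,
                        format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("arff" if path.suffix.lower() == ".arff" else "csv")
    if fmt == "csv":
        df = table.values.copy()
        df["class"] = (
            table.labels.astype(str) if table.labels is not None else "?"
        )
        df.to_csv(path, index=True, float_format="%.12g")
    elif fmt == "arff":
        _write_arff(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_arff(table: FeatureTable, path: Path) -> None:
    classes = (
        sorted(set(table.labels.astype(str))) if table.labels is not None else ["?"]
    )
    lines = [f"@relation sensor_features_{table.transform}", ""]
    for name in table.feature_names:
        lines.append(f"@attribute {name} numeric")
    if table.labels is not None:
        lines.append("@attribute class {" + ",".join(classes) + "}")
    else:
        lines.append("@attribute class {unknown}")
    lines.append("")
    lines.append("@data")
    values = table.values.to_numpy()
    for i in range(len(values)):
        row = ",".join(repr(float(v)) for v in values[i])
        cls = str(table.labels.iloc[i]) if table.labels is not None else "?"
        lines.append(f"{row},{cls}")
    path.write_text("\n".join(lines) + "\n")


def read_feature_table(path: str | Path, transform: str = "raw") -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if path.suffix.lower() == ".arff":
        return _read_arff(path, transform)
    df = pd.read_csv(path, index_col=[0, 1])
    labels = None
    if "class" in df.columns:
        cls = df.pop("class")
        if not (cls == "?").all():
            labels = cls
    return FeatureTable(df, transform=transform, labels=labels)


def _read_arff(path: Path, transform: str) -> FeatureTable:
    names: list[str] = []
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@attribute"):
            names.append(line.split()[1])
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            parts = line.split(",")
            rows.append([float(p) for p in parts[:-1]])
            labels.append(parts[-1].strip())
    if not rows:
        raise ValueError(f"no data rows in {path}")
    feat_names = names[:-1]  # last attribute is the class
    index = pd.MultiIndex.from_tuples(
        [(path.stem, f"row{i}") for i in range(len(rows))],
        names=["trial_id", "sensor_id"],
    )
    df = pd.DataFrame(rows, columns=feat_names, index=index)
    lab = None
    if any(l != "?" for l in labels):
        lab = pd.Series(labels, index=index, name="class")
    return FeatureTable(df, transform=transform, labels=lab)


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

def serialize_model(model, path: str | Path) -> None:
    """Write an identification model to a JSON file."""
    path = Path(path)
    payload = {"schema_version": MODEL_SCHEMA_VERSION}
    payload.update(model.to_dict())
    path.write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    """Load an identification model written by :func:`serialize_model`."""
    from .identify import IdentificationModel  # late import: avoids a cycle

    path = Path(path)
    payload = json.loads(path.read_text())
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return IdentificationModel.from_dict(payload)
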