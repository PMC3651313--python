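"""Per-sensor feature extraction and the rank / normalize / raw transforms.

For each of the three kinematic signals — free acceleration ``a``, angular
velocity ``w`` and angular acceleration ``alpha`` — 19 features are computed
per sensor over the analysis window:

* RMS of the magnitude and of the x-, y-, z-components (4),
* variance of the magnitude and of the x-, y-, z-components (4),
* sum and maximum of the Pearson correlations of each component with the
  same component of every *other* sensor of the trial (8), i.e. row sums
  and row maxima of the cross-sensor correlation matrix with the diagonal
  excluded,
* inter-axis correlations x-y, x-z, y-z within the sensor (3),

for 57 features in total.  The cross-sensor families require a known sensor
configuration; the configuration-unknown ("raw") mode drops them, leaving 33.

Feature values are made comparable across subjects and walking speeds by
per-trial fractional ranking ("1 2.5 2.5 4": ties receive the mean of their
ordinal ranks); per-trial z-scoring is available as an alternative.

This module also provides the correlation features used for left/right
disambiguation: trunk orientation angles (trapezoidal integration of angular
velocity plus linear detrending), the 45 limb-versus-trunk correlations, and
the adjacent-segment correlation components for the distal segments.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend
from scipy.stats import rankdata

from .preprocess import GlobalSignals, PreprocessedTrial
from .trial_io import FeatureTable

__all__ = [
    "SIGNALS",
    "AXES",
    "STEP3_COMPONENTS",
    "feature_names",
    "count_features",
    "per_sensor_features",
    "cross_sensor_features",
    "extract_trial_features",
    "build_feature_table",
    "fractional_rank",
    "transform_table",
    "trunk_orientation",
    "step2_features",
    "step3_component_series",
]

SIGNALS = ("a", "w", "alpha")
AXES = ("x", "y", "z")
_COMPONENTS = ("mag", "x", "y", "z")

#: Adjacent-segment correlation component used for left/right identification
#: of each distal segment class: (reference class, signal, axis index).
STEP3_COMPONENTS: dict[str, tuple[str, str, int]] = {
    "shoulder": ("upper_arm", "a", 2),   # a_z
    "forearm": ("upper_arm", "a", 0),    # a_x
    "hand": ("forearm", "a", 1),         # a_y
    "lower_leg": ("upper_leg", "a", 0),  # a_x
    "foot": ("lower_leg", "a", 0),       # a_x
}

#: Order in which distal segments are resolved, so that each reference
#: segment's side is already known when it is needed.
STEP3_ORDER = ("shoulder", "forearm", "hand", "lower_leg", "foot")


def feature_names(mode: str = "rank") -> list[str]:
    """The stable feature registry, in extraction order."""
    names: list[str] = []
    for sig in SIGNALS:
        for comp in _COMPONENTS:
            names.append(f"RMS_{comp}_{sig}")
        for comp in _COMPONENTS:
            names.append(f"Var_{comp}_{sig}")
        if mode != "raw":
            for comp in _COMPONENTS:
                names.append(f"SumCC_{comp}_{sig}")
            for comp in _COMPONENTS:
                names.append(f"MaxCC_{comp}_{sig}")
        for pair in ("xy", "xz", "yz"):
            names.append(f"IAC_{pair}_{sig}")
    return names


def count_features(mode: str = "rank") -> int:
    """57 in rank/normalize modes; 33 in configuration-unknown raw mode."""
    return len(feature_names(mode))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) when either side is constant."""
    sx, sy = np.std(x), np.std(y)
    if sx < 1e-12 or sy < 1e-12:
        warnings.warn("zero-variance series: correlation set to 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _series(sig: GlobalSignals, name: str) -> np.ndarray:
    return {"a": sig.acc, "w": sig.gyr, "alpha": sig.angacc}[name]


def _components(arr: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "mag": np.linalg.norm(arr, axis=1),
        "x": arr[:, 0],
        "y": arr[:, 1],
        "z": arr[:, 2],
    }


def per_sensor_features(sig: GlobalSignals) -> dict[str, float]:
    """RMS, variance and inter-axis correlation families of one sensor."""
    if len(sig.acc) < 2:
        raise ValueError("need at least 2 samples in the analysis window")
    out: dict[str, float] = {}
    for name in SIGNALS:
        arr = _series(sig, name)
        comps = _components(arr)
        for comp, series in comps.items():
            out[f"RMS_{comp}_{name}"] = float(np.sqrt(np.mean(series**2)))
        for comp, series in comps.items():
            out[f"Var_{comp}_{name}"] = float(np.var(series))
        for pair in ("xy", "xz", "yz"):
            i, j = AXES.index(pair[0]), AXES.index(pair[1])
            out[f"IAC_{pair}_{name}"] = _safe_corr(arr[:, i], arr[:, j])
    return out


def cross_sensor_features(
    signals: Mapping[str, GlobalSignals],
) -> dict[str, dict[str, float]]:
    """Row sums and maxima of the cross-sensor correlation matrices.

    For every signal and component, the Pearson correlations between all
    sensor pairs form a symmetric matrix; each sensor receives the sum and
    the maximum of its row with the diagonal (self-correlation) excluded.
    """
    ids = list(signals)
    if len(ids) < 2:
        raise ValueError(
            "cross-sensor features require at least 2 sensors "
            "(use the raw feature mode for single-sensor data)"
        )
    out: dict[str, dict[str, float]] = {sid: {} for sid in ids}
    for name in SIGNALS:
        comp_stack = {
            sid: _components(_series(signals[sid], name)) for sid in ids
        }
        for comp in _COMPONENTS:
            mat = np.empty((len(ids), len(ids)))
            np.fill_diagonal(mat, 0.0)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    c = _safe_corr(
                        comp_stack[ids[i]][comp], comp_stack[ids[j]][comp]
                    )
                    mat[i, j] = mat[j, i] = c
            row_sum = mat.sum(axis=1)
            np.fill_diagonal(mat, -np.inf)
            row_max = mat.max(axis=1)
            for i, sid in enumerate(ids):
                out[sid][f"SumCC_{comp}_{name}"] = float(row_sum[i])
                out[sid][f"MaxCC_{comp}_{name}"] = float(row_max[i])
    return out


def extract_trial_features(pre: PreprocessedTrial) -> pd.DataFrame:
    """All 57 raw feature values for every sensor of one trial.

    Returns a DataFrame indexed by ``(trial_id, sensor_id)`` with columns in
    registry order (cross-sensor families included when the trial has more
    than one sensor).
    """
    per = {sid: per_sensor_features(sig) for sid, sig in pre.signals.items()}
    if len(pre.signals) >= 2:
        cross = cross_sensor_features(pre.signals)
        for sid in per:
            per[sid].update(cross[sid])
        cols = feature_names("rank")
    else:
        cols = feature_names("raw")
    trial_id = pre.trial.trial_id if pre.trial is not None else "trial"
    index = pd.MultiIndex.from_tuples(
        [(trial_id, sid) for sid in per], names=["trial_id", "sensor_id"]
    )
    return pd.DataFrame([[per[sid][c] for c in cols] for sid in per],
                        index=index, columns=cols)


def build_feature_table(
    pres: list[PreprocessedTrial], transform: str = "rank"
) -> FeatureTable:
    """Pool per-trial features, apply a transform, and attach class labels
    where trials carry ground truth."""
    frames = [extract_trial_features(p) for p in pres]
    values = pd.concat(frames)
    labels = None
    rows: list[str | None] = []
    for p in pres:
        t = p.trial
        for sid in p.signals:
            rows.append(
                t.labels[sid].segment_class
                if (t is not None and t.labels is not None)
                else None
            )
    if all(r is not None for r in rows):
        labels = pd.Series(rows, index=values.index, name="class")
    table = FeatureTable(values, transform="raw", labels=labels)
    return transform_table(table, transform)


def fractional_rank(values: np.ndarray) -> np.ndarray:
    """Ascending fractional ranks ("1 2.5 2.5 4"): ties get the mean of the
    ordinal ranks they span, so ranks always sum to n(n+1)/2."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values cannot be ranked")
    return rankdata(values, method="average")


def transform_table(table: FeatureTable, mode: str) -> FeatureTable:
    """Per-trial fractional ranking, per-trial z-scoring, or raw values.

    Raw mode drops the cross-sensor correlation families, which are
    meaningless when the configuration (and hence the identity of the other
    sensors) is unknown.
    """
    if mode == "raw":
        keep = [c for c in table.values.columns
                if not (c.startswith("SumCC") or c.startswith("MaxCC"))]
        return FeatureTable(table.values[keep].copy(), transform="raw",
                            labels=table.labels)
    if mode == "rank":
        ranked = table.values.groupby(level="trial_id", sort=False).transform(
            lambda col: fractional_rank(col.to_numpy())
        )
        return FeatureTable(ranked, transform="rank", labels=table.labels)
    if mode == "normalize":
        def _z(col: pd.Series) -> pd.Series:
            std = col.std(ddof=0)
            if std < 1e-12:
                return col * 0.0
            return (col - col.mean()) / std

        normed = table.values.groupby(level="trial_id", sort=False).transform(_z)
        return FeatureTable(normed, transform="normalize", labels=table.labels)
    raise ValueError(f"unknown transform {mode!r}")


# ---------------------------------------------------------------------------
# Left/right correlation features (steps 2 and 3)
# ---------------------------------------------------------------------------

def _integrate_detrend(series: np.ndarray, fs: float) -> np.ndarray:
    integ = cumulative_trapezoid(series, dx=1.0 / fs, axis=0, initial=0.0)
    return detrend(integ, axis=0, type="linear")


def trunk_orientation(gyr: np.ndarray, fs: float) -> np.ndarray:
    """Trunk orientation angles about x, y, z by trapezoidal integration of
    the global-frame angular velocity, followed by linear detrending.

    Valid for the pelvis and sternum, whose orientation excursions during
    walking are small, so the full strapdown integration is unnecessary and
    detrending removes the slow integration drift.
    """
    return _integrate_detrend(np.asarray(gyr, dtype=float), fs)


def step2_features(limb: GlobalSignals, trunk_theta: np.ndarray) -> dict[str, float]:
    """The 45 limb-versus-trunk correlations used for left/right calls.

    Limb series: acceleration, velocity (trapezoidal integral of
    acceleration, detrended), angular velocity, angular acceleration and
    orientation (integral of angular velocity, detrended) — five signal
    types, three axes each — correlated with the three trunk orientation
    components.
    """
    fs = limb.fs
    series = {
        "acc": limb.acc,
        "vel": _integrate_detrend(limb.acc, fs),
        "gyr": limb.gyr,
        "angacc": limb.angacc,
        "orient": _integrate_detrend(limb.gyr, fs),
    }
    out: dict[str, float] = {}
    for tname, arr in series.items():
        for ai, axis in enumerate(AXES):
            for ti, taxis in enumerate(AXES):
                out[f"cc_{tname}{axis}_theta{taxis}"] = _safe_corr(
                    arr[:, ai], trunk_theta[:, ti]
                )
    return out


def step3_component_series(sig: GlobalSignals, segment_class: str) -> np.ndarray:
    """The signal component on which a distal segment class is correlated
    with its (already-resolved) neighbour class."""
    _, signal, axis = STEP3_COMPONENTS[segment_class]
    return _series(sig, signal)[:, axis]
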