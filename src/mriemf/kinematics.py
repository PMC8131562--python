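"""Marker-trajectory ingestion, smoothing, centroids and velocities.

A :class:`Recording` holds labelled 3D marker trajectories sampled at a
fixed rate (100 Hz in the measurement protocol).  Trajectories are smoothed
with a zero-phase low-pass filter, segment centroids are formed as per-frame
means of marker clusters, and velocities are obtained by central finite
differences.  The end product, :class:`PointKinematics`, carries position
and velocity series for the 23 representative body points.

Supported file formats: an internal CSV dialect (columns ``time_s`` and
``<label>_x/_y/_z`` in metres), TRC (tab-separated, millimetres) and,
when the optional ``ezc3d`` dependency is installed, C3D.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import UnivariateSpline

from . import markers as mk


class FormatError(ValueError):
    """Raised when a trajectory file cannot be parsed."""


@dataclass
class Recording:
    """Labelled marker trajectories at a fixed sampling rate.

    ``markers`` maps label -> (T, 3) position array in metres.  NaNs mark
    occluded (gap) frames.
    """

    rate: float
    markers: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker series have unequal lengths: {lengths}")
        if lengths and next(iter(lengths)) < 2:
            raise ValueError("recordings need at least 2 frames")
        for label, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {label!r} is not a (T, 3) series")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def labels(self) -> list[str]:
        return list(self.markers)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass(frozen=True)
class SegmentClusterMap:
    """Segment name -> marker labels (>= 3 per cluster)."""

    clusters: dict[str, tuple[str, ...]]
    calibration_only: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, labels in self.clusters.items():
            if len(labels) < 3:
                raise ValueError(f"cluster {name!r} has fewer than 3 markers")
            overlap = set(labels) & self.calibration_only
            if overlap:
                raise ValueError(
                    f"calibration-only markers {sorted(overlap)} in dynamic "
                    f"cluster {name!r}"
                )


def default_cluster_map() -> SegmentClusterMap:
    return SegmentClusterMap(
        clusters=dict(mk.SEGMENT_CLUSTERS),
        calibration_only=frozenset(mk.CALIBRATION_ONLY_MARKERS),
    )


@dataclass(frozen=True)
class ExposurePointSet:
    """The ordered exposure points with their head subset."""

    points: tuple[mk.ExposurePoint, ...] = mk.EXPOSURE_POINTS
    head_numbers: frozenset[int] = mk.HEAD_POINT_NUMBERS

    def __post_init__(self) -> None:
        if len(self.points) != 23:
            raise ValueError("exposure point set must contain exactly 23 points")
        if len(self.head_numbers) != 5:
            raise ValueError("head subset must contain exactly 5 points")

    @property
    def head_indices(self) -> np.ndarray:
        """0-based indices of the head points within ``points``."""
        return np.array(
            [i for i, p in enumerate(self.points) if p.number in self.head_numbers]
        )


@dataclass
class PointKinematics:
    """Smoothed positions and velocities of the exposure points.

    ``positions`` and ``velocities`` are (T, n_points, 3) arrays [m, m/s].
    """

    rate: float
    positions: np.ndarray
    velocities: np.ndarray
    point_set: ExposurePointSet

    def __post_init__(self) -> None:
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must share a shape")
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise ValueError("kinematics contain non-finite values")

    @property
    def speeds(self) -> np.ndarray:
        """(T, n_points) point speeds |v| [m/s]."""
        return np.linalg.norm(self.velocities, axis=2)


# ---------------------------------------------------------------------------
# file I/O


def write_recording_csv(rec: Recording, path) -> None:
    data = {"time_s": rec.time}
    for label, arr in rec.markers.items():
        data[f"{label}_x"] = arr[:, 0]
        data[f"{label}_y"] = arr[:, 1]
        data[f"{label}_z"] = arr[:, 2]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def _read_csv(path) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("internal CSV requires a time_s column")
    labels = []
    for col in df.columns:
        if col.endswith("_x"):
            labels.append(col[:-2])
    if not labels:
        raise FormatError("no <label>_x columns found")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise FormatError("recording has fewer than 2 frames")
    rate = 1.0 / np.median(np.diff(t))
    markers = {}
    for label in labels:
        cols = [f"{label}_{ax}" for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"missing columns for marker {label!r}: {missing}")
        markers[label] = df[cols].to_numpy(dtype=float)
    return Recording(rate=round(rate, 6), markers=markers)


def write_recording_trc(rec: Recording, path) -> None:
    """Write a minimal TRC file (tab-separated, millimetres)."""
    labels = rec.labels
    n = rec.n_frames
    rate = rec.rate
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(labels)}\tmm\t{rate:g}\t1\t{n}\n")
        header = "Frame#\tTime" + "".join(f"\t{lab}\t\t" for lab in labels)
        fh.write(header.rstrip("\t") + "\n")
        sub = "\t" + "".join(
            f"\tX{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels))
        )
        fh.write(sub + "\n")
        t = rec.time
        for i in range(n):
            row = [str(i + 1), f"{t[i]:.5f}"]
            for lab in labels:
                p = rec.markers[lab][i] * 1000.0  # m -> mm
                row.extend(f"{c:.5f}" for c in p)
            fh.write("\t".join(row) + "\n")


def _read_trc(path) -> Recording:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError("not a TRC file")
    meta_keys = lines[1].split("\t")
    meta_vals = lines[2].split("\t")
    meta = dict(zip(meta_keys, meta_vals))
    rate = float(meta["DataRate"])
    units = meta.get("Units", "mm").strip().lower()
    scale = 1e-3 if units == "mm" else 1.0
    labels = [c for c in lines[3].split("\t")[2:] if c.strip()]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append([float(p) if p.strip() else np.nan for p in parts[2:]])
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != 3 * len(labels):
        raise FormatError(
            f"TRC data width {data.shape[1]} != 3 x {len(labels)} markers"
        )
    markers = {
        lab: data[:, 3 * i : 3 * i + 3] * scale for i, lab in enumerate(labels)
    }
    return Recording(rate=rate, markers=markers)


def _read_c3d(path) -> Recording:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "C3D support requires the optional 'ezc3d' dependency "
            "(pip install mriemf[c3d]); TRC and CSV are supported natively"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = c3d["parameters"]["POINT"]["UNITS"]["value"][0].strip().lower()
    scale = 1e-3 if units == "mm" else 1.0
    pts = c3d["data"]["points"]  # (4, n_markers, T)
    markers = {
        lab: pts[:3, i, :].T * scale for i, lab in enumerate(labels)
    }
    return Recording(rate=rate, markers=markers)


def read_recording(path, format: str | None = None) -> Recording:
    """Read a marker recording; format inferred from the suffix if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    readers = {"csv": _read_csv, "trc": _read_trc, "c3d": _read_c3d}
    if fmt not in readers:
        raise FormatError(f"unknown recording format {fmt!r}")
    rec = readers[fmt](path)
    rec.meta["source"] = str(path)
    return rec


# ---------------------------------------------------------------------------
# processing


def fill_gaps(series: np.ndarray, max_gap: int = 10) -> np.ndarray:
    """Linearly interpolate NaN gaps of at most ``max_gap`` frames."""
    series = np.array(series, dtype=float)
    bad = ~np.isfinite(series).all(axis=1)
    if not bad.any():
        return series
    if bad[0] or bad[-1]:
        raise ValueError("gap at recording boundary cannot be interpolated")
    # longest run of consecutive gap frames
    runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
    if runs.size and runs.max() > max_gap:
        raise ValueError(
            f"gap of {runs.max()} frames exceeds the {max_gap}-frame limit"
        )
    idx = np.arange(len(series))
    for k in range(3):
        series[bad, k] = np.interp(idx[bad], idx[~bad], series[~bad, k])
    return series


def smooth(
    series: np.ndarray,
    rate: float,
    cutoff_hz: float = 6.0,
    order: int = 4,
    method: str = "butterworth",
) -> np.ndarray:
    """Zero-phase low-pass smoothing of a position series.

    The default is a 4th-order Butterworth filter at 6 Hz applied
    forward-backward (no phase shift).  ``method='spline'`` instead fits a
    cross-validated smoothing spline per coordinate.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n = series.shape[0]
    if n < 7:
        raise ValueError("series too short to smooth (need >= 7 frames)")
    if not np.isfinite(series).all():
        raise ValueError("series contains non-finite values; fill gaps first")
    if method == "spline":
        t = np.arange(n) / rate
        out = np.empty_like(series)
        for k in range(series.shape[1]):
            y = series[:, k]
            # noise variance from second differences sets the penalty
            sigma2 = np.var(np.diff(y, 2)) / 6.0
            out[:, k] = UnivariateSpline(t, y, s=n * sigma2)(t)
        return out
    if method != "butterworth":
        raise ValueError(f"unknown smoothing method {method!r}")
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        return series.copy()
    sos = signal.butter(order, cutoff_hz / nyq, output="sos")
    padlen = min(3 * (2 * order + 1), n - 1)
    return signal.sosfiltfilt(sos, series, axis=0, padlen=padlen)


def cluster_centroid(rec: Recording, labels) -> np.ndarray:
    """Per-frame arithmetic mean position of the cluster markers."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("a cluster needs at least 3 markers")
    missing = [lab for lab in labels if lab not in rec.markers]
    if missing:
        raise KeyError(f"cluster markers missing from recording: {missing}")
    return np.mean([rec.markers[lab] for lab in labels], axis=0)


def differentiate(series: np.ndarray, rate: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the endpoints) [m/s]."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    return np.gradient(series, 1.0 / rate, axis=0)


def extract_exposure_points(
    rec: Recording,
    clusters: SegmentClusterMap | None = None,
    point_set: ExposurePointSet | None = None,
    cutoff_hz: float = 6.0,
    smoothing: str = "butterworth",
) -> PointKinematics:
    """Smoothed positions and velocities of the 23 exposure points.

    Marker trajectories are gap-filled and low-pass smoothed, cluster
    centroids are taken on the smoothed markers, and each point trajectory
    is differentiated into a velocity series.
    """
    clusters = clusters or default_cluster_map()
    point_set = point_set or ExposurePointSet()

    smoothed = Recording(
        rate=rec.rate,
        markers={
            lab: smooth(fill_gaps(arr), rec.rate, cutoff_hz, method=smoothing)
            for lab, arr in rec.markers.items()
            if lab not in clusters.calibration_only
        },
        meta=dict(rec.meta),
    )
    pos = np.empty((rec.n_frames, len(point_set.points), 3))
    for i, point in enumerate(point_set.points):
        if point.kind == "centroid":
            if point.source not in clusters.clusters:
                raise KeyError(
                    f"point {point.number} ({point.description}): segment "
                    f"{point.source!r} not in the cluster map"
                )
            pos[:, i] = cluster_centroid(
                smoothed, clusters.clusters[point.source]
            )
        else:
            if point.source not in smoothed.markers:
                raise KeyError(
                    f"point {point.number} ({point.description}): marker "
                    f"{point.source!r} absent from the recording"
                )
            pos[:, i] = smoothed.markers[point.source]
    vel = differentiate(pos, rec.rate)
    return PointKinematics(
        rate=rec.rate, positions=pos, velocities=vel, point_set=point_set
    )
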