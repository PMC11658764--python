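"""Domain types, calibrated image/trace I/O, configuration and tidy tables.

Conventions used throughout the package:

* pixel indexing is 0-based ``(row, col)``; the physical coordinate of a
  pixel center is ``index * pixel_size_um`` (x = col, y = row);
* time windows are half-open ``[start, end)`` in seconds, so every frame
  belongs to at most one window;
* output tables are tidy CSV, one row per (cell, frame-or-window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "BinaryMask",
    "ClusterRecord",
    "ClusterSet",
    "IntensityTrace",
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "write_table",
    "load_config",
]

#: default analysis time windows, seconds: minutes 0-1, 5-6 and 9-10
DEFAULT_WINDOWS_S: tuple[tuple[float, float], ...] = (
    (0.0, 60.0),
    (300.0, 360.0),
    (540.0, 600.0),
)


@dataclass(frozen=True)
class ImageStack:
    """A calibrated T x C x Y x X intensity stack.

    Parameters
    ----------
    data
        Array indexed ``[frame, channel, row, col]``; finite and >= 0.
    pixel_size_um
        Physical pixel size in micrometres (> 0).
    frame_interval_s
        Seconds between consecutive frames (> 0).
    channel_names
        One label per channel, e.g. ``("gcamp", "lfa1")``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4:
            raise ValueError(f"stack must be 4-D (T,C,Y,X); got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("stack intensities must be finite")
        if data.size and data.min() < 0:
            raise ValueError("stack intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        names = tuple(self.channel_names)
        if len(names) != data.shape[1]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[1]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def channel(self, name: str) -> np.ndarray:
        """Return the (T, Y, X) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.data[:, idx]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean (row, col) mask with its physical calibration."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D; got shape {px.shape}")
        if px.dtype != bool:
            px = px.astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ClusterRecord:
    """One segmented nanocluster within a frame."""

    cluster_id: int
    centroid_xy_um: tuple[float, float]
    area_um2: float
    pixel_count: int
    mean_intensity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterSet:
    """All nanoclusters of one frame.

    Invariants: areas respect the configured minimum, ``pixel_count *
    pixel_size_um**2 == area_um2`` and ids are unique within the frame.
    """

    frame_index: int
    records: tuple[ClusterRecord, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        ids = [r.cluster_id for r in recs]
        if len(ids) != len(set(ids)):
            raise ValueError("cluster ids must be unique within a frame")
        for r in recs:
            expected = r.pixel_count * self.pixel_size_um**2
            if not np.isclose(r.area_um2, expected):
                raise ValueError(
                    f"cluster {r.cluster_id}: area {r.area_um2} != "
                    f"pixel_count x pixel_size^2 = {expected}"
                )
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centroids_um(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in micrometres."""
        if not self.records:
            return np.empty((0, 2))
        return np.array([r.centroid_xy_um for r in self.records], dtype=float)


@dataclass(frozen=True)
class IntensityTrace:
    """A single-cell intensity time series (arbitrary units)."""

    times_s: np.ndarray
    values: np.ndarray
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.times_s.size else 0.0


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis parameters with their standard defaults.

    Defaults follow the acquisition/analysis conventions the pipeline was
    designed around: a 0.15 um^2 minimum nanocluster area, Otsu automatic
    thresholding, Ripley radii 0.5-5.5 um, a z >= 3 event gate and the
    minute 0-1 / 5-6 / 9-10 summary windows.
    """

    min_cluster_area_um2: float = 0.15
    threshold_method: str = "otsu"
    radii_um: tuple[float, ...] = tuple(np.arange(1, 12) * 0.5)  # 0.5 .. 5.5
    n_envelope_sims: int = 100
    z_threshold: float = 3.0
    time_windows_s: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_S
    min_ripley_points: int = 10
    baseline_window_s: float = 180.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cluster_area_um2 <= 0:
            raise ValueError("min_cluster_area_um2 must be > 0")
        radii = tuple(float(r) for r in self.radii_um)
        if not radii or radii[0] <= 0 or any(
            b <= a for a, b in zip(radii, radii[1:])
        ):
            raise ValueError("radii_um must be positive and strictly increasing")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if self.n_envelope_sims < 2:
            raise ValueError("n_envelope_sims must be >= 2")
        windows = tuple((float(a), float(b)) for a, b in self.time_windows_s)
        for a, b in windows:
            if b <= a:
                raise ValueError(f"empty time window [{a}, {b})")
        ordered = sorted(windows)
        for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
            if a1 < b0:
                raise ValueError("time windows must be disjoint")
        object.__setattr__(self, "radii_um", radii)
        object.__setattr__(self, "time_windows_s", windows)

    @staticmethod
    def window_label(window: tuple[float, float]) -> str:
        return f"min {window[0] / 60:g}-{window[1] / 60:g}"


def read_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF movie into a calibrated :class:`ImageStack`.

    3-D files are interpreted as (T, Y, X) single-channel movies, 4-D files
    as (T, C, Y, X).  Explicit calibration arguments always win over file
    metadata, which is frequently absent or wrong in exported stacks.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image stack {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    elif data.ndim != 4:
        raise ValueError(
            f"{path}: shape {data.shape} is not interpretable as (T,C,Y,X) or (T,Y,X)"
        )
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[1]))
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=tuple(channel_names),
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a TIFF file (axes TCYX)."""
    tifffile.imwrite(Path(path), stack.data, metadata={"axes": "TCYX"})


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write tidy records to CSV with a deterministic column order.

    An empty record list still produces a header-only CSV when ``columns``
    is given (otherwise an empty file with no header, since the schema is
    unknowable).  Missing values are written as empty cells, never as 0.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=list(columns) if columns else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(Path(path), index=False)


_CONFIG_KEYS = {
    "min_cluster_area_um2",
    "threshold_method",
    "radii_um",
    "n_envelope_sims",
    "z_threshold",
    "time_windows_s",
    "min_ripley_points",
    "baseline_window_s",
    "rng_seed",
}


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON document.

    Keys absent from the document take the defaults; unknown keys raise.
    Validation failures name the offending key.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config {path} must be a key/value document")
    doc.update(overrides)
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "radii_um" in doc:
        doc["radii_um"] = tuple(float(r) for r in doc["radii_um"])
    if "time_windows_s" in doc:
        doc["time_windows_s"] = tuple(
            (float(a), float(b)) for a, b in doc["time_windows_s"]
        )
    try:
        return AnalysisConfig(**doc)
    except ValueError as exc:
        raise ValueError(f"invalid config ({sorted(doc)}): {exc}") from exc


def config_to_dict(config: AnalysisConfig) -> dict:
    """JSON-serializable snapshot of a config (used by run manifests)."""
    return {
        "min_cluster_area_um2": config.min_cluster_area_um2,
        "threshold_method": config.threshold_method,
        "radii_um": list(config.radii_um),
        "n_envelope_sims": config.n_envelope_sims,
        "z_threshold": config.z_threshold,
        "time_windows_s": [list(w) for w in config.time_windows_s],
        "min_ripley_points": config.min_ripley_points,
        "baseline_window_s": config.baseline_window_s,
        "rng_seed": config.rng_seed,
    }


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
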