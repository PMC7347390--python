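"""Core data containers and on-disk formats shared by every pipeline stage.

The central exchange object is :class:`BehaviorRecord`: per-frame time
series of posture, locomotion and validity flags, plus the discrete event
trains (egg-laying, defecation, pharyngeal pumps) detected downstream.
Records are stored as an HDF5 container (one dataset per field) with a JSON
sidecar of metadata, so 400k-frame overnight recordings stream in one pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
from PIL import Image

SCHEMA_VERSION = 1

#: seconds per day; frame budget arithmetic uses this constant
SECONDS_PER_DAY = 86_400

VENTRAL_SIDES = ("left", "right", "unknown")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing.

    Parameters
    ----------
    frame_rate : float
        Nominal frames per second (default 20; below this pharyngeal
        pumping is undersampled, above it adds little).
    pixel_size : float
        Microns per pixel at the object plane (default 1.44).
    frame_shape : tuple of int
        Frame size as (rows, cols) in pixels.
    """

    frame_rate: float = 20.0
    pixel_size: float = 1.44
    frame_shape: tuple[int, int] = (1024, 1024)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class EventTrain:
    """A sorted train of discrete behavioral events.

    ``counts`` (eggs per event, >= 1) is defined only for ``kind='egg'``:
    multiple eggs are occasionally laid simultaneously.
    """

    kind: str
    times: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("egg", "defecation", "pump"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if np.any(np.diff(times) < 0):
            raise ValueError("event times must be sorted ascending")
        if self.kind == "egg":
            counts = (
                np.ones(times.size, dtype=int)
                if self.counts is None
                else np.asarray(self.counts, dtype=int)
            )
            if counts.shape != times.shape or (counts.size and counts.min() < 1):
                raise ValueError("egg counts must parallel times and be >= 1")
            object.__setattr__(self, "counts", counts)
        elif self.counts is not None:
            raise ValueError("counts are defined only for egg events")

    @property
    def n_events(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LawnBoundary:
    """Closed planar polygon (µm) tracing the bacterial lawn perimeter."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("lawn boundary needs >= 3 planar vertices")
        from shapely.geometry import Polygon

        if not Polygon(verts).is_valid:
            raise ValueError("lawn boundary polygon is self-intersecting")
        object.__setattr__(self, "vertices", verts)


@dataclass
class BehaviorRecord:
    """Per-frame behavioral time series for one animal.

    All per-frame arrays share a single length ``n_frames``.  Lengths are in
    µm (the pixel→µm conversion is applied exactly once, at extraction
    time); times in seconds.  Missing values are carried by explicit
    validity masks, not sentinels: ``valid_posture`` is False on frames
    whose centerline was self-intersecting (omega bends), ``valid_widths``
    on frames whose width profile could not be measured.
    """

    timestamps: np.ndarray  # (n,) s, strictly increasing
    centroid: np.ndarray  # (n, 2) µm
    posture: np.ndarray  # (n, 14) rad, mean-centered where valid
    orientation: np.ndarray  # (n,) rad, mean body angle
    valid_posture: np.ndarray  # (n,) bool
    half_widths: np.ndarray  # (n, 2, 30) px
    valid_widths: np.ndarray  # (n,) bool
    worm_length: np.ndarray  # (n,) µm
    worm_area: np.ndarray  # (n,) px^2
    centerline_intensity: np.ndarray  # (n, p) head-to-tail profile
    ventral_side: str = "unknown"
    events: dict[str, EventTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        for name in (
            "centroid",
            "posture",
            "orientation",
            "valid_posture",
            "half_widths",
            "valid_widths",
            "worm_length",
            "worm_area",
            "centerline_intensity",
        ):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} frames, expected {n}")
            setattr(self, name, arr)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.ventral_side not in VENTRAL_SIDES:
            raise ValueError(f"ventral_side must be one of {VENTRAL_SIDES}")
        if n and np.any(self.worm_length[np.isfinite(self.worm_length)] < 0):
            raise ValueError("worm_length must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(len(self.timestamps))

    @property
    def frame_rate(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames to infer a frame rate")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n_frames else 0.0

    def with_events(self, **trains: EventTrain) -> "BehaviorRecord":
        events = dict(self.events)
        events.update(trains)
        return replace(self, events=events)


def frames_per_day(config: AcquisitionConfig) -> int:
    """Number of frames acquired in 24 h of continuous recording.

    At the nominal 20 Hz this is 1,728,000 frames (~1.7 million images per
    animal per day), which sets the storage budget for overnight tracking.
    """
    return int(round(config.frame_rate * SECONDS_PER_DAY))


# ---------------------------------------------------------------------------
# frame sequences


def read_frame_sequence(
    directory: str | Path, manifest: str | Path | pd.DataFrame | None = None
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(timestamp_s, image)`` pairs from a directory of frames.

    The manifest (CSV with columns ``filename,time_s``, defaulting to
    ``manifest.csv`` inside ``directory``) is the sole source of timing:
    filenames are never parsed for timestamps.  Frames are yielded in
    manifest order, which must be strictly increasing in time.
    """
    directory = Path(directory)
    if manifest is None:
        manifest = directory / "manifest.csv"
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if not {"filename", "time_s"} <= set(manifest.columns):
        raise ValueError("manifest needs columns 'filename' and 'time_s'")
    times = manifest["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("manifest timestamps are not strictly increasing")
    for fname, t in zip(manifest["filename"], times):
        path = directory / str(fname)
        if not path.exists():
            raise FileNotFoundError(f"frame file missing: {path} (time {t} s)")
        with Image.open(path) as im:
            img = np.asarray(im.convert("L"))
        yield float(t), img


def write_frame_sequence(
    directory: str | Path,
    frames: Iterator[tuple[float, np.ndarray]] | list[tuple[float, np.ndarray]],
    fmt: str = "png",
) -> pd.DataFrame:
    """Write frames + manifest in the layout `read_frame_sequence` expects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t, img) in enumerate(frames):
        fname = f"frame_{i:06d}.{fmt}"
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(
            directory / fname
        )
        rows.append({"filename": fname, "time_s": float(t)})
    manifest = pd.DataFrame(rows, columns=["filename", "time_s"])
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# record I/O

_ARRAY_FIELDS = (
    "timestamps",
    "centroid",
    "posture",
    "orientation",
    "valid_posture",
    "half_widths",
    "valid_widths",
    "worm_length",
    "worm_area",
    "centerline_intensity",
)


def write_record(record: BehaviorRecord, path: str | Path) -> None:
    """Write a record as HDF5 (one dataset per field) + a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for name in _ARRAY_FIELDS:
            f.create_dataset(name, data=getattr(record, name))
        ev = f.create_group("events")
        for kind, train in record.events.items():
            g = ev.create_group(kind)
            g.create_dataset("times", data=train.times)
            if train.counts is not None:
                g.create_dataset("counts", data=train.counts)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "ventral_side": record.ventral_side,
        "n_frames": record.n_frames,
        "event_kinds": sorted(record.events),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_record(path: str | Path) -> BehaviorRecord:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"record schema version {version} != supported {SCHEMA_VERSION}"
            )
        arrays = {name: f[name][()] for name in _ARRAY_FIELDS}
        arrays["valid_posture"] = arrays["valid_posture"].astype(bool)
        arrays["valid_widths"] = arrays["valid_widths"].astype(bool)
        events = {}
        for kind in f["events"]:
            g = f["events"][kind]
            counts = g["counts"][()] if "counts" in g else None
            events[kind] = EventTrain(kind=kind, times=g["times"][()], counts=counts)
    sidecar_path = path.with_suffix(".json")
    ventral = "unknown"
    if sidecar_path.exists():
        ventral = json.loads(sidecar_path.read_text()).get("ventral_side", "unknown")
    return BehaviorRecord(ventral_side=ventral, events=events, **arrays)


def write_events_csv(events: dict[str, EventTrain], path: str | Path) -> None:
    """Export event trains as a flat CSV (kind, time_s, count)."""
    rows = []
    for kind in sorted(events):
        train = events[kind]
        counts = train.counts if train.counts is not None else np.ones(train.n_events, int)
        for t, c in zip(train.times, counts):
            rows.append({"kind": kind, "time_s": t, "count": int(c)})
    pd.DataFrame(rows, columns=["kind", "time_s", "count"]).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> dict[str, EventTrain]:
    df = pd.read_csv(path)
    out = {}
    for kind, grp in df.groupby("kind"):
        grp = grp.sort_values("time_s")
        counts = grp["count"].to_numpy() if kind == "egg" else None
        out[str(kind)] = EventTrain(
            kind=str(kind), times=grp["time_s"].to_numpy(), counts=counts
        )
    return out


def write_lawn_csv(lawn: LawnBoundary, path: str | Path) -> None:
    pd.DataFrame(lawn.vertices, columns=["x_um", "y_um"]).to_csv(path, index=False)


def read_lawn_csv(path: str | Path) -> LawnBoundary:
    df = pd.read_csv(path)
    return LawnBoundary(vertices=df[["x_um", "y_um"]].to_numpy(dtype=float))
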