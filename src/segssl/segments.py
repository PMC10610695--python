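"""Segment-structured accelerometer data: records, windowing, pseudo-labels.

A *segment* is one contiguous tri-axial recording containing exactly one
activity (the activity label itself is optional and only the evaluation stage
ever reads it). Segments are sliced into fixed-length *instance windows* by a
sliding window; every window receives two pseudo-labels: a globally unique
instance label and the label of the segment it came from, so that ``M ≤ N``
(segments never outnumber windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SegmentRecord",
    "WindowingConfig",
    "InstanceWindow",
    "DatasetIndex",
    "slide_windows",
    "assign_pseudo_labels",
    "read_segment_dir",
    "write_segment_dir",
]


@dataclass
class SegmentRecord:
    """One contiguous single-activity recording.

    ``samples`` is a T×3 float array (axis order x, y, z) at
    ``sampling_rate_hz``. ``activity`` is optional ground truth used only for
    evaluation; the unsupervised pipeline never reads it.
    """

    segment_id: int
    sampling_rate_hz: float
    samples: np.ndarray
    subject_id: str | None = None
    activity: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.segment_id < 0:
            raise ValueError(f"segment_id must be >= 0, got {self.segment_id}")
        if self.sampling_rate_hz <= 0:
            raise ValueError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(
                f"segment {self.segment_id}: samples must be T x 3, "
                f"got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError(f"segment {self.segment_id}: empty samples")
        if not np.isfinite(self.samples).all():
            raise ValueError(
                f"segment {self.segment_id}: samples contain non-finite values"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters: window length L and stride S, in samples.

    Defaults are non-overlapping 256-sample windows (2.56 s at 100 Hz).
    """

    window_length: int = 256
    stride: int = 256
    standardize: bool = False  # per-channel z-scoring from training statistics

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError(f"window_length must be >= 1, got {self.window_length}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


@dataclass
class InstanceWindow:
    """An L×3 window slice carrying instance and segment pseudo-labels."""

    instance_label: int
    segment_label: int
    window: np.ndarray
    activity: str | None = None


@dataclass
class DatasetIndex:
    """All instance windows of a dataset plus the label bookkeeping.

    ``n_instances`` (N) counts windows, ``n_segments`` (M) counts segments
    that produced at least one window; always M ≤ N.
    """

    instances: list[InstanceWindow]
    segment_to_instances: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_segments(self) -> int:
        return len(self.segment_to_instances)

    @property
    def window_length(self) -> int:
        return self.instances[0].window.shape[0]

    def windows_array(self) -> np.ndarray:
        """Stack all windows into an (N, L, 3) array, instance-label order."""
        return np.stack([iw.window for iw in self.instances])

    def segment_labels(self) -> np.ndarray:
        return np.array([iw.segment_label for iw in self.instances], dtype=np.int64)

    def instance_labels(self) -> np.ndarray:
        return np.array([iw.instance_label for iw in self.instances], dtype=np.int64)

    def activities(self) -> list[str | None]:
        return [iw.activity for iw in self.instances]


def slide_windows(
    segment: SegmentRecord, config: WindowingConfig
) -> list[np.ndarray]:
    """Slice a segment into L×3 windows at offsets 0, S, 2S, …

    Returns ``floor((T−L)/S)+1`` windows when T ≥ L; a segment shorter than
    one window yields the empty list and a warning (never padded — padding
    would fabricate signal).
    """
    if not np.isfinite(segment.samples).all():  # defensive; record validates too
        raise ValueError(f"segment {segment.segment_id}: non-finite samples")
    L, S = config.window_length, config.stride
    T = segment.n_samples
    if T < L:
        warnings.warn(
            f"segment {segment.segment_id} has {T} samples < window length {L}; "
            "dropped",
            stacklevel=2,
        )
        return []
    n = (T - L) // S + 1
    return [segment.samples[o : o + L].copy() for o in range(0, n * S, S)]


def assign_pseudo_labels(
    segments: list[SegmentRecord], config: WindowingConfig
) -> DatasetIndex:
    """Window every segment and assign instance/segment pseudo-labels.

    Instance labels enumerate windows in (segment order, offset order);
    segment labels enumerate — contiguously from 0 — only the segments that
    yielded at least one window.
    """
    instances: list[InstanceWindow] = []
    seg_map: dict[int, list[int]] = {}
    next_segment = 0
    for seg in segments:
        wins = slide_windows(seg, config)
        if not wins:
            continue
        s = next_segment
        next_segment += 1
        seg_map[s] = []
        for w in wins:
            i = len(instances)
            instances.append(
                InstanceWindow(
                    instance_label=i,
                    segment_label=s,
                    window=w,
                    activity=seg.activity,
                )
            )
            seg_map[s].append(i)
    if not instances:
        raise ValueError(
            "no usable windows: every segment is shorter than the window length"
        )
    index = DatasetIndex(instances=instances, segment_to_instances=seg_map)
    if config.standardize:
        stacked = index.windows_array()
        mu = stacked.mean(axis=(0, 1))
        sd = stacked.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        for iw in index.instances:
            iw.window = (iw.window - mu) / sd
    return index


# --------------------------------------------------------------------- I/O

_METADATA_NAME = "metadata.yaml"


def write_segment_dir(segments: list[SegmentRecord], path: str | Path) -> None:
    """Write segments as ``<segment_id>.csv`` files plus ``metadata.yaml``.

    CSV columns are ``t,ax,ay,az`` with t in seconds from the segment start.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"segments": {}}
    for seg in segments:
        t = np.arange(seg.n_samples) / seg.sampling_rate_hz
        df = pd.DataFrame(
            {
                "t": t,
                "ax": seg.samples[:, 0],
                "ay": seg.samples[:, 1],
                "az": seg.samples[:, 2],
            }
        )
        df.to_csv(path / f"{seg.segment_id}.csv", index=False, float_format="%.12g")
        entry: dict = {"sampling_rate_hz": float(seg.sampling_rate_hz)}
        if seg.subject_id is not None:
            entry["subject_id"] = seg.subject_id
        if seg.activity is not None:
            entry["activity"] = seg.activity
        meta["segments"][int(seg.segment_id)] = entry
    with open(path / _METADATA_NAME, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_segment_dir(path: str | Path) -> list[SegmentRecord]:
    """Read a segment directory written by :func:`write_segment_dir`.

    Records are returned sorted by ``segment_id``. Raises on a missing
    metadata file, malformed CSV, or a non-monotone time column.
    """
    path = Path(path)
    meta_path = path / _METADATA_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} not found: not a segment directory")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    entries = meta.get("segments", {})
    if not entries:
        raise ValueError(f"no segments found in {path}")
    records: list[SegmentRecord] = []
    for sid in sorted(int(k) for k in entries):
        entry = entries[sid] if sid in entries else entries[str(sid)]
        csv_path = path / f"{sid}.csv"
        if not csv_path.exists():
            raise FileNotFoundError(f"segment {sid}: missing CSV file {csv_path}")
        df = pd.read_csv(csv_path)
        expected = ["t", "ax", "ay", "az"]
        if list(df.columns) != expected:
            raise ValueError(
                f"segment {sid}: malformed CSV, expected columns {expected}, "
                f"got {list(df.columns)}"
            )
        t = df["t"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError(f"segment {sid}: non-monotone time column")
        records.append(
            SegmentRecord(
                segment_id=sid,
                sampling_rate_hz=float(entry["sampling_rate_hz"]),
                samples=df[["ax", "ay", "az"]].to_numpy(),
                subject_id=entry.get("subject_id"),
                activity=entry.get("activity"),
            )
        )
    return records
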