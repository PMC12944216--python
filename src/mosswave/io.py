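"""Core array containers and file I/O for the analysis pipeline.

Conventions: arrays are indexed ``(frame, row, col)`` = ``(t, y, x)``; reported
stack shapes follow the microscopy convention ``(m, n, t)`` with *m* rows
(image height) and *n* columns (width).  Time in seconds is
``frame_index * frame_interval_s``.  All writers are deterministic (fixed field
order, fixed float formatting) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimelapseStack",
    "StimulusProtocol",
    "ROILabelMap",
    "read_stack",
    "write_stack",
    "crop",
    "read_protocol",
    "write_protocol",
    "write_results",
    "read_traces",
]

_FLOAT_FMT = "%.6g"


@dataclass
class TimelapseStack:
    """A 3D grayscale timelapse: ``data[t, y, x]`` plus acquisition metadata.

    pixel_size_um
        Lateral sampling in micrometres per pixel (default 2.9, i.e.
        0.345 pixels/µm).
    frame_interval_s
        Seconds between consecutive frames (default 1 frame/s).
    origin
        Frame index corresponding to recording time zero.
    """

    data: np.ndarray
    pixel_size_um: float = 2.9
    frame_interval_s: float = 1.0
    origin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D (t, y, x); got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"stack dimensions must all be >= 1; got {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def shape_mnt(self) -> tuple[int, int, int]:
        """Shape as (m rows, n columns, t frames)."""
        t, m, n = self.data.shape
        return m, n, t

    def times(self) -> np.ndarray:
        """Recording time of each frame in seconds."""
        return (np.arange(self.n_frames) - self.origin) * self.frame_interval_s

    def crop(self, rect: tuple[int, int, int, int]) -> "TimelapseStack":
        return crop(self, rect)


def crop(stack: TimelapseStack, rect: tuple[int, int, int, int]) -> TimelapseStack:
    """Crop every frame to ``rect = (y0, x0, height, width)``.

    The rectangle must lie fully inside the frame; metadata is preserved.
    """
    y0, x0, h, w = (int(v) for v in rect)
    m, n = stack.frame_shape
    if h < 1 or w < 1:
        raise ValueError(f"crop extent must be >= 1 pixel; got height={h}, width={w}")
    if y0 < 0 or x0 < 0 or y0 + h > m or x0 + w > n:
        raise ValueError(
            f"crop rect {(y0, x0, h, w)} exceeds frame bounds {(m, n)}"
        )
    return TimelapseStack(
        data=stack.data[:, y0 : y0 + h, x0 : x0 + w].copy(),
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        origin=stack.origin,
    )


@dataclass
class StimulusProtocol:
    """On/off times (seconds) of stimulus pulses within a recording.

    Pulses must be sorted, non-overlapping and contained in
    ``[0, recording_duration_s]``.
    """

    pulses: list[tuple[float, float]] = field(default_factory=list)
    recording_duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.pulses = [(float(a), float(b)) for a, b in self.pulses]
        prev_off = 0.0
        for i, (on, off) in enumerate(self.pulses):
            if not (0.0 <= on < off <= self.recording_duration_s):
                raise ValueError(
                    f"pulse {i} ({on}, {off}) outside [0, {self.recording_duration_s}]"
                )
            if on < prev_off:
                raise ValueError(f"pulse {i} overlaps or precedes the previous pulse")
            prev_off = off

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([on for on, _ in self.pulses], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([off for _, off in self.pulses], dtype=float)

    def stimulus_state(self, times: np.ndarray) -> np.ndarray:
        """Boolean stimulus-on state sampled at the given times."""
        t = np.asarray(times, dtype=float)
        state = np.zeros(t.shape, dtype=bool)
        for on, off in self.pulses:
            state |= (t >= on) & (t < off)
        return state

    def to_json(self, path: str | Path) -> None:
        write_protocol(self, path)


@dataclass
class ROILabelMap:
    """Integer partition of foreground pixels: 0 = background, 1..K = ROI ids."""

    labels: np.ndarray
    pixel_size_um: float = 2.9

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("ROI label ids must be contiguous 1..K")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max(initial=0))

    def areas(self) -> np.ndarray:
        """Pixel area of each ROI, indexed 0..K-1 for ids 1..K."""
        return np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)[1:]


# ---------------------------------------------------------------------------
# TIFF I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> TimelapseStack:
    """Read a multi-page TIFF timelapse.

    Metadata is taken from an optional ``<name>.tif.meta.json`` sidecar written
    by :func:`write_stack`, overridable by the keyword arguments; otherwise the
    package defaults (2.9 µm/pixel, 1 s/frame) apply.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise OSError(f"failed to read TIFF stack {path} (page 0): {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 2.9)
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else meta.get("frame_interval_s", 1.0)
    )
    return TimelapseStack(data=data, pixel_size_um=px, frame_interval_s=dt,
                          origin=int(meta.get("origin", 0)))


def write_stack(stack: TimelapseStack, path: str | Path, sidecar: bool = True) -> Path:
    """Write an ImageJ-compatible multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data
    imagej = data.dtype in (np.uint8, np.uint16, np.float32)
    tifffile.imwrite(path, data, imagej=imagej)
    if sidecar:
        meta = {
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
            "origin": stack.origin,
        }
        _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path


def write_label_map(labels: ROILabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.labels.astype(np.uint16), imagej=True)
    return path


def read_label_map(path: str | Path, pixel_size_um: float = 2.9) -> ROILabelMap:
    return ROILabelMap(labels=tifffile.imread(path).astype(np.int32),
                       pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# Protocol JSON


def read_protocol(path: str | Path) -> StimulusProtocol:
    obj = json.loads(Path(path).read_text())
    pulses = [(p["on_s"], p["off_s"]) for p in obj["pulses"]]
    return StimulusProtocol(pulses=pulses,
                            recording_duration_s=obj["recording_duration_s"])


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> Path:
    path = Path(path)
    obj = {
        "pulses": [{"on_s": on, "off_s": off} for on, off in protocol.pulses],
        "recording_duration_s": protocol.recording_duration_s,
    }
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")
    return path


# ---------------------------------------------------------------------------
# Result tables


def write_results(traces, waves, path: str | Path, manifest_extra: dict | None = None) -> dict:
    """Write a run's outputs: trace matrix CSV, wave table CSV, JSON manifest.

    ``traces`` is an ``ROITraceSet`` and ``waves`` a ``WaveTable``; both must
    reference the same ROI ids.  Returns the manifest dict.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trace_ids = [int(i) for i in traces.roi_ids]
    wave_ids = sorted({int(i) for i in waves.roi_ids()})
    orphans = sorted(set(wave_ids) - set(trace_ids))
    if orphans:
        raise ValueError(f"wave table references ROI ids absent from traces: {orphans}")

    times = traces.times()
    tdf = pd.DataFrame({"time_s": times})
    for i, roi in enumerate(trace_ids):
        tdf[f"roi_{roi}"] = traces.dff[i]
    tdf.to_csv(path / "traces.csv", index=False, float_format=_FLOAT_FMT)

    wdf = waves.to_dataframe()
    wdf.to_csv(path / "waves.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {
        "n_rois": len(trace_ids),
        "n_frames": int(len(times)),
        "n_waves": int(len(wdf)),
        "roi_ids": trace_ids,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (path / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def read_traces(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a trace CSV back: returns (times_s, DataFrame of roi columns)."""
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    return times, df
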