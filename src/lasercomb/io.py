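"""Recording container and flat-binary I/O.

A recording is a channels x samples matrix of extracellular voltage in
microvolts at a fixed sampling rate (nominally 20 kHz). On disk it is a
float32 little-endian channel-major flat binary next to a JSON sidecar
holding the metadata; no vendor formats are parsed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "SegmentLabel", "read_recording", "write_recording"]

SEGMENT_KINDS = ("laser_off_pre", "laser_on", "laser_off_post")


@dataclass
class Recording:
    """Multichannel voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    sampling_rate : float
        Samples per second; must be positive.
    channel_ids : list of str, optional
        Labels, one per channel; defaults to ``ch0 .. chN-1``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds (index / sampling_rate + t0)."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"no channel {channel_id!r} in {self.channel_ids}") from None
        return self.samples[idx]


@dataclass(frozen=True)
class SegmentLabel:
    """Half-open time segment [start, end) tagged by laser condition."""

    kind: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"kind must be one of {SEGMENT_KINDS}, got {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")

    def sample_slice(self, sampling_rate: float, t0: float = 0.0) -> slice:
        a = int(round((self.start - t0) * sampling_rate))
        b = int(round((self.end - t0) * sampling_rate))
        return slice(max(a, 0), b)

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return (t >= self.start) & (t < self.end)


def validate_segments(segments: list[SegmentLabel]) -> None:
    """Require ordered, non-overlapping segments."""
    for a, b in zip(segments, segments[1:]):
        if b.start < a.end:
            raise ValueError(f"segments overlap or out of order: {a} then {b}")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as ``<path>.dat`` (float32 LE, channel-major) + ``<path>.json``.

    ``path`` is the basename; the two files share it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(recording.samples, dtype="<f4")
    data.tofile(path.with_suffix(".dat"))
    meta = {
        "sampling_rate_hz": recording.sampling_rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "units": "uV",
        "duration_s": recording.duration,
        "t0_s": recording.t0,
        "channel_ids": recording.channel_ids,
        "dtype": "float32",
        "byte_order": "little",
        "layout": "channel_major",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a flat-binary recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    binary = path.with_suffix(".dat")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    if not binary.exists():
        raise FileNotFoundError(f"missing binary {binary}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate_hz", "n_channels", "units"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field {key!r}")
    if meta["units"] != "uV":
        raise ValueError(
            f"sidecar units {meta['units']!r} not 'uV'; no implicit conversion is performed"
        )
    raw = np.fromfile(binary, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0:
        raise ValueError(
            f"binary length {raw.size} not divisible by n_channels={n_ch}"
        )
    n_samples = raw.size // n_ch
    if "n_samples" in meta and int(meta["n_samples"]) != n_samples:
        raise ValueError(
            f"binary holds {n_samples} samples/channel but sidecar says {meta['n_samples']}"
        )
    return Recording(
        samples=raw.reshape(n_ch, n_samples),
        sampling_rate=float(meta["sampling_rate_hz"]),
        channel_ids=list(meta.get("channel_ids", [])),
        t0=float(meta.get("t0_s", 0.0)),
    )
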