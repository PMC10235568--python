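"""Containers for continuous EEG recordings and seizure annotations.

The package works internally in seconds relative to the start of a
recording; absolute timestamps appear only at the I/O boundary
(ISO-8601 onset files, the record's ``start_time``).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecord",
    "SeizureAnnotation",
    "AnnotationError",
    "read_annotations",
    "write_annotations",
]


class AnnotationError(ValueError):
    """Raised for unsorted, duplicate or out-of-record seizure annotations."""


@dataclasses.dataclass
class EEGRecord:
    """A continuous multichannel scalp EEG recording.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitude in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_names : sequence of str
        Unique electrode labels (10-20 system for clinical data).
    start_time : datetime
        Absolute time of the first sample.
    """

    signal: np.ndarray
    fs: float
    channel_names: Sequence[str]
    start_time: dt.datetime

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValueError("sampling frequency must be positive")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def time_of(self, seconds: float) -> dt.datetime:
        """Absolute timestamp of an offset in seconds from record start."""
        return self.start_time + dt.timedelta(seconds=float(seconds))

    # -- simple on-disk container: raw float32 array + JSON sidecar -------
    def save(self, path: str | pathlib.Path) -> None:
        """Write the record as ``<path>.npy`` plus ``<path>.json`` sidecar."""
        path = pathlib.Path(path)
        np.save(path.with_suffix(".npy"), self.signal.astype(np.float32))
        meta = {
            "fs": float(self.fs),
            "channel_names": list(self.channel_names),
            "start_time": self.start_time.isoformat(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "EEGRecord":
        path = pathlib.Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        signal = np.load(path.with_suffix(".npy"))
        return cls(
            signal=signal,
            fs=meta["fs"],
            channel_names=meta["channel_names"],
            start_time=dt.datetime.fromisoformat(meta["start_time"]),
        )


@dataclasses.dataclass
class SeizureAnnotation:
    """Ordered seizure onset (and optional offset) timestamps for one patient."""

    onsets: Sequence[dt.datetime]
    offsets: Sequence[dt.datetime] | None = None

    def __post_init__(self) -> None:
        self.onsets = list(self.onsets)
        for a, b in zip(self.onsets, self.onsets[1:]):
            if not b > a:
                raise AnnotationError(f"onsets not strictly increasing: {a!r} !< {b!r}")
        if self.offsets is not None:
            self.offsets = list(self.offsets)
            if len(self.offsets) != len(self.onsets):
                raise AnnotationError("offsets and onsets differ in length")
            for on, off in zip(self.onsets, self.offsets):
                if not off > on:
                    raise AnnotationError(f"offset {off!r} not after onset {on!r}")

    @property
    def n_seizures(self) -> int:
        return len(self.onsets)

    def onsets_s(self, reference: dt.datetime) -> np.ndarray:
        """Onset times in seconds relative to ``reference``."""
        return np.array([(t - reference).total_seconds() for t in self.onsets])

    def validate_within(self, record: EEGRecord) -> None:
        """Raise :class:`AnnotationError` for onsets outside the record span."""
        end = record.time_of(record.duration_s)
        for t in self.onsets:
            if t < record.start_time or t > end:
                raise AnnotationError(
                    f"onset {t.isoformat()} outside record span "
                    f"[{record.start_time.isoformat()}, {end.isoformat()}]"
                )

    @classmethod
    def from_seconds(
        cls,
        onsets_s: Sequence[float],
        reference: dt.datetime,
        offsets_s: Sequence[float] | None = None,
    ) -> "SeizureAnnotation":
        mk = lambda s: reference + dt.timedelta(seconds=float(s))
        return cls(
            onsets=[mk(s) for s in onsets_s],
            offsets=None if offsets_s is None else [mk(s) for s in offsets_s],
        )


def write_annotations(ann: SeizureAnnotation, path: str | pathlib.Path) -> None:
    """Write onsets (and offsets, if present) as an ISO-8601 CSV.

    Header is ``onset_iso8601`` or ``onset_iso8601,offset_iso8601``.
    """
    cols = {"onset_iso8601": [t.isoformat() for t in ann.onsets]}
    if ann.offsets is not None:
        cols["offset_iso8601"] = [t.isoformat() for t in ann.offsets]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_annotations(
    path: str | pathlib.Path, record: EEGRecord | None = None
) -> SeizureAnnotation:
    """Read an ISO-8601 onset CSV; an empty file yields an empty annotation.

    If ``record`` is given, onsets are checked to lie inside its span.
    """
    path = pathlib.Path(path)
    if path.stat().st_size == 0:
        return SeizureAnnotation(onsets=[])
    df = pd.read_csv(path)
    if len(df) == 0:
        return SeizureAnnotation(onsets=[])
    onsets = [dt.datetime.fromisoformat(s) for s in df["onset_iso8601"]]
    offsets = None
    if "offset_iso8601" in df.columns:
        offsets = [dt.datetime.fromisoformat(s) for s in df["offset_iso8601"]]
    ann = SeizureAnnotation(onsets=onsets, offsets=offsets)
    if record is not None:
        ann.validate_within(record)
    return ann
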