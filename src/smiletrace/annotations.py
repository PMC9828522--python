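"""Reference smile annotations and post-video task schedules.

Manual coders mark each distinct smile episode by its onset and cessation
frames (a distinct episode is preceded and followed by a smile-free period
of at least two seconds).  This module holds those reference intervals,
expands them to frame-wise boolean labels for calibration, and parses the
schedule of confounder tasks (speaking, yawning, posed expressions, ...)
performed after the stimulus video.

Interval bounds are inclusive frame indices, matching the coders'
frame-wise convention.  Annotation CSVs carry ``session_id, onset_frame,
offset_frame``; task CSVs carry ``name, start_s, end_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

TASK_NAMES = frozenset(
    {
        "speaking",
        "yawning",
        "coughing",
        "mouth_covering",
        "anger",
        "sadness",
        "fear",
        "surprise",
        "disgust",
        "smiling",
        "neutral",
    }
)


@dataclass(frozen=True, order=True)
class ReferenceInterval:
    """One manually coded smile episode, inclusive frame bounds."""

    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if self.onset_frame < 0:
            raise DataError(f"negative onset frame {self.onset_frame}")
        if self.offset_frame < self.onset_frame:
            raise DataError(
                f"offset {self.offset_frame} precedes onset {self.onset_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping reference intervals for one session."""

    session_id: str
    intervals: list[ReferenceInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.onset_frame <= a.offset_frame:
                raise DataError(
                    f"session {self.session_id!r}: intervals "
                    f"({a.onset_frame},{a.offset_frame}) and "
                    f"({b.onset_frame},{b.offset_frame}) overlap"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class TaskEvent:
    """One scheduled post-video task, timed in seconds on the session clock."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.name not in TASK_NAMES:
            raise DataError(f"unknown task name {self.name!r}")
        if not self.end > self.start:
            raise DataError(f"task {self.name!r}: end must exceed start")


def read_annotations(source: Union[str, TextIO], session_id: str = "") -> AnnotationTrack:
    """Parse an annotation CSV into a validated :class:`AnnotationTrack`.

    An empty body is legal (a session with zero smiles).  With a ``fps``
    column dialect in seconds, use :func:`seconds_to_frames` first.

    Raises
    ------
    FormatError
        Missing required column.
    DataError
        Overlapping intervals or offset before onset.
    """
    df = pd.read_csv(source)
    df.columns = [c.strip() for c in df.columns]
    for col in ("session_id", "onset_frame", "offset_frame"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) == 0:
        return AnnotationTrack(session_id=session_id or "session", intervals=[])
    sid = session_id or str(df["session_id"].iloc[0])
    sub = df[df["session_id"].astype(str) == sid] if session_id else df
    intervals = [
        ReferenceInterval(int(r.onset_frame), int(r.offset_frame))
        for r in sub.itertuples()
    ]
    return AnnotationTrack(session_id=sid, intervals=intervals)


def write_annotations(track: AnnotationTrack, sink: Union[str, TextIO]) -> None:
    """Write a track in the annotation CSV dialect (header always present)."""
    pd.DataFrame(
        {
            "session_id": [track.session_id] * len(track),
            "onset_frame": [iv.onset_frame for iv in track],
            "offset_frame": [iv.offset_frame for iv in track],
        }
    ).to_csv(sink, index=False)


def seconds_to_frames(onset_s: float, offset_s: float, fps: float) -> ReferenceInterval:
    """Convert a seconds-based interval to frames by rounding to nearest."""
    return ReferenceInterval(int(round(onset_s * fps)), int(round(offset_s * fps)))


def frame_labels(track: AnnotationTrack, n_frames: int) -> np.ndarray:
    """Expand reference intervals to a frame-wise boolean label vector.

    ``label[i]`` is True iff frame ``i`` lies inside some reference interval
    (inclusive bounds).  The number of True labels equals the summed
    interval lengths.

    Raises
    ------
    DataError
        If an interval extends beyond ``n_frames``.
    """
    labels = np.zeros(n_frames, dtype=bool)
    for iv in track:
        if iv.offset_frame >= n_frames:
            raise DataError(
                f"interval ({iv.onset_frame},{iv.offset_frame}) exceeds "
                f"series length {n_frames}"
            )
        labels[iv.onset_frame : iv.offset_frame + 1] = True
    return labels


def read_task_schedule(source: Union[str, TextIO]) -> list[TaskEvent]:
    """Parse a task-schedule CSV into validated, time-sorted events.

    Raises
    ------
    FormatError
        Missing required column.
    DataError
        Overlapping events or unknown task names.
    """
    df = pd.read_csv(source)
    df.columns = [c.strip() for c in df.columns]
    for col in ("name", "start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    events = sorted(
        (TaskEvent(str(r.name), float(r.start_s), float(r.end_s)) for r in df.itertuples()),
        key=lambda e: e.start,
    )
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise DataError(f"tasks {a.name!r} and {b.name!r} overlap in time")
    return events


def write_task_schedule(events: Sequence[TaskEvent], sink: Union[str, TextIO]) -> None:
    """Write a task schedule in the task CSV dialect."""
    pd.DataFrame(
        {
            "name": [e.name for e in events],
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
        }
    ).to_csv(sink, index=False)
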