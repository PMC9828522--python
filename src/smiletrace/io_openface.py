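"""Reading and writing facial action-unit time series.

The on-disk format is the CSV dialect emitted by automated facial-behaviour
toolkits such as OpenFace: one row per video frame with at minimum the
columns ``frame``, ``timestamp``, ``confidence``, ``success``, ``AU06_r``,
``AU12_r`` and ``AU25_c``.  Header names may carry stray whitespace (they do
in the wild); extra columns are ignored.  AU6 (cheek raiser) and AU12 (lip
corner puller) are continuous intensities on the 0-5 FACS scale; AU25 (lips
apart, i.e. teeth visible) is dichotomous.

The in-memory container is :class:`AUTimeSeries`, a column-oriented record
of one session.  Timestamps are frame *start* times; a frame spans
``[t, t + 1/fps)`` and all interval arithmetic downstream is half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO, Union

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

REQUIRED_COLUMNS = ("frame", "timestamp", "success", "AU06_r", "AU12_r", "AU25_c")


@dataclass
class AUTimeSeries:
    """Per-frame AU record of one recording session.

    Attributes
    ----------
    session_id : str
        Identifier of the session (typically the video file stem).
    frame_index : ndarray of int
        Frame numbers, contiguous from 0 unless the reader flagged gaps.
    timestamp : ndarray of float
        Frame start times in seconds, strictly increasing.
    confidence : ndarray of float
        Tracker confidence in [0, 1].
    success : ndarray of bool
        Whether the face was tracked in the frame.  Untracked frames are
        retained (the time base stays intact) but are treated as
        sub-threshold by the detector.
    au6, au12 : ndarray of float
        Continuous AU intensities on the 0-5 scale.
    au25 : ndarray of bool
        Teeth visible in the frame.
    fps : float
        Frames per second, inferred from the timestamps when not given.
    """

    session_id: str
    frame_index: np.ndarray
    timestamp: np.ndarray
    confidence: np.ndarray
    success: np.ndarray
    au6: np.ndarray
    au12: np.ndarray
    au25: np.ndarray
    fps: float = field(default=0.0)

    def __post_init__(self) -> None:
        n = len(self.frame_index)
        if n == 0:
            raise DataError("AUTimeSeries requires at least one frame")
        for name in ("timestamp", "confidence", "success", "au6", "au12", "au25"):
            if len(getattr(self, name)) != n:
                raise DataError(f"column {name!r} length mismatch")
        if n >= 2 and not np.all(np.diff(self.timestamp) > 0):
            raise DataError(
                f"session {self.session_id!r}: timestamps are not strictly increasing"
            )
        if np.any((self.au6 < 0) | (self.au6 > 5)) or np.any(
            (self.au12 < 0) | (self.au12 > 5)
        ):
            raise DataError("AU intensities must lie on the 0-5 scale")
        if self.fps <= 0 and n >= 2:
            self.fps = infer_frame_rate(self)

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def duration(self) -> float:
        """Session length in seconds (each frame spans 1/fps)."""
        return self.n_frames / self.fps

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of frames with successful face tracking."""
        return self.success.astype(bool)


def read_au_csv(source: Union[str, TextIO], session_id: str = "") -> AUTimeSeries:
    """Read an AU time series from an OpenFace-dialect CSV.

    Parameters
    ----------
    source : path or text stream
    session_id : str
        Session identifier to attach; defaults to the file stem when a path
        is given.

    Raises
    ------
    FormatError
        If a required column is absent.
    DataError
        If timestamps are not strictly increasing.
    """
    if isinstance(source, str) and not session_id:
        session_id = source.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    # round_trip parser: text -> float64 is exact, so write/read is identity
    df = pd.read_csv(source, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    df = df.sort_values("frame", kind="stable")
    return AUTimeSeries(
        session_id=session_id or "session",
        frame_index=df["frame"].to_numpy(dtype=np.int64),
        timestamp=df["timestamp"].to_numpy(dtype=float),
        confidence=df["confidence"].to_numpy(dtype=float),
        success=df["success"].to_numpy(dtype=float) >= 0.5,
        au6=df["AU06_r"].to_numpy(dtype=float),
        au12=df["AU12_r"].to_numpy(dtype=float),
        au25=df["AU25_c"].to_numpy(dtype=float) >= 0.5,
    )


def infer_frame_rate(ts: AUTimeSeries) -> float:
    """Frame rate as the reciprocal of the median inter-frame interval.

    The median makes the estimate robust to isolated dropped frames.
    Invariant under uniform time shifts.
    """
    if len(ts.timestamp) < 2:
        raise DataError("at least two frames are needed to infer a frame rate")
    dt = float(np.median(np.diff(ts.timestamp)))
    if dt <= 0:
        raise DataError("non-positive median inter-frame interval")
    return 1.0 / dt


def write_au_csv(ts: AUTimeSeries, sink: Union[str, TextIO]) -> None:
    """Write an AU time series in the OpenFace output dialect.

    Round-trips exactly with :func:`read_au_csv` on all modelled fields.
    Refuses to write an empty (headerless-body) series.
    """
    if ts.n_frames == 0:
        raise FormatError("refusing to write a series with no frames")
    df = pd.DataFrame(
        {
            "frame": ts.frame_index,
            "timestamp": ts.timestamp,
            "confidence": ts.confidence,
            "success": ts.success.astype(int),
            "AU06_r": ts.au6,
            "AU12_r": ts.au12,
            "AU25_c": ts.au25.astype(int),
        }
    )
    # 17 significant digits: lossless text round-trip for float64
    df.to_csv(sink, index=False, float_format="%.17g")


def dumps_au_csv(ts: AUTimeSeries) -> str:
    """Serialise a series to a CSV string (convenience for tests/CLI)."""
    buf = io.StringIO()
    write_au_csv(ts, buf)
    return buf.getvalue()
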