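"""Smile-episode detection from AU time series.

A frame counts as smiling when both the Duchenne marker AU6 (cheek raiser)
and AU12 (lip corner puller) are *strictly above* their activation
thresholds.  Maximal runs of smiling frames form episodes; an episode only
ends when either AU stays sub-threshold for at least the stand-by time
(default 2 s), so runs separated by a shorter gap are merged into a single
episode and the gap frames are absorbed into it.

Per episode the detector reports onset, duration (at the resolution of one
frame interval), mean AU6 activation (genuineness), mean AU12 activation
(intensity) and the percentage of frames with teeth visible (AU25, "tooth
show").  Per session it reports episode frequency (episodes/minute) and the
relative smile time, i.e. the percentage of the session spent smiling.

Frames where face tracking failed are treated as sub-threshold: they never
start a smile and they accumulate gap time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io_openface import AUTimeSeries

#: Operating thresholds selected by Youden-index maximisation on the
#: reference validation sample: AU6 > 0.5 and AU12 > 1.5.
DEFAULT_TH1 = 0.5
DEFAULT_TH2 = 1.5
DEFAULT_STANDBY = 2.0


@dataclass(frozen=True)
class DetectionConfig:
    """Detector parameters.

    th1 : AU6 activation threshold on the 0-5 scale (default 0.5).
    th2 : AU12 activation threshold on the 0-5 scale (default 1.5).
    standby : sub-threshold duration in seconds that terminates an episode
        (default 2.0); shorter gaps are merged.
    """

    th1: float = DEFAULT_TH1
    th2: float = DEFAULT_TH2
    standby: float = DEFAULT_STANDBY

    def __post_init__(self) -> None:
        if not (0 <= self.th1 <= 5 and 0 <= self.th2 <= 5):
            raise ConfigError("thresholds must lie in [0, 5]")
        if self.standby <= 0:
            raise ConfigError("stand-by time must be positive")


@dataclass(frozen=True)
class SmileEpisode:
    """One detected smile episode (inclusive frame bounds)."""

    index: int
    onset_frame: int
    offset_frame: int
    onset_time: float
    duration: float
    mean_au6: float
    mean_au12: float
    tooth_show: float

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1


@dataclass(frozen=True)
class SessionSummary:
    """Session-level smile statistics.

    Episode-mean fields are None when no episode was detected.
    """

    n_episodes: int
    episodes_per_minute: float
    mean_duration: Optional[float]
    relative_smile_time: float
    mean_au6: Optional[float]
    mean_au12: Optional[float]
    mean_tooth_show: Optional[float]

    def to_dict(self) -> dict:
        return {
            "n_episodes": self.n_episodes,
            "episodes_per_minute": self.episodes_per_minute,
            "mean_duration_s": self.mean_duration,
            "relative_smile_time_pct": self.relative_smile_time,
            "mean_au6": self.mean_au6,
            "mean_au12": self.mean_au12,
            "mean_tooth_show_pct": self.mean_tooth_show,
        }


def classify_frames(
    ts: AUTimeSeries, config: DetectionConfig = DetectionConfig()
) -> np.ndarray:
    """Frame-wise smile classification.

    Frame ``i`` is a smile frame iff ``au6[i] > th1`` and ``au12[i] > th2``
    (strict inequalities) and the face was tracked in the frame.
    """
    return (ts.au6 > config.th1) & (ts.au12 > config.th2) & ts.valid_mask()


def segment_episodes(
    smile: np.ndarray, fps: float, standby: float = DEFAULT_STANDBY
) -> list[tuple[int, int]]:
    """Group smile frames into episodes, merging short gaps.

    Two consecutive runs of smile frames are merged — with the gap frames
    absorbed into the episode — iff the gap duration (gap frame count / fps)
    is strictly less than ``standby``; a gap of exactly the stand-by time
    splits them.  Returns inclusive (onset_frame, offset_frame) spans.
    """
    if fps <= 0:
        raise ConfigError("fps must be positive")
    if standby <= 0:
        raise ConfigError("stand-by time must be positive")
    smile = np.asarray(smile, dtype=bool)
    if smile.size == 0 or not smile.any():
        return []
    # run boundaries via sign changes of the padded indicator
    padded = np.diff(np.concatenate(([0], smile.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive
    spans: list[tuple[int, int]] = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        gap_frames = s - spans[-1][1] - 1
        if gap_frames / fps < standby:
            spans[-1] = (spans[-1][0], int(e))
        else:
            spans.append((int(s), int(e)))
    return spans


def episode_metrics(
    ts: AUTimeSeries, span: tuple[int, int], index: int = 1
) -> SmileEpisode:
    """Quantify one episode over its inclusive frame span.

    Means of AU6 and AU12 are taken across the *entire* episode, merged-gap
    frames included; tooth show is the percentage of the episode's frames
    with AU25 active.  Duration is (frame count) / fps, i.e. a multiple of
    the frame interval.
    """
    onset, offset = span
    if onset < 0 or offset >= ts.n_frames or offset < onset:
        raise DataError(f"span ({onset},{offset}) outside series of {ts.n_frames} frames")
    sl = slice(onset, offset + 1)
    n = offset - onset + 1
    return SmileEpisode(
        index=index,
        onset_frame=onset,
        offset_frame=offset,
        onset_time=float(ts.timestamp[onset]),
        duration=n / ts.fps,
        mean_au6=float(np.mean(ts.au6[sl])),
        mean_au12=float(np.mean(ts.au12[sl])),
        tooth_show=100.0 * float(np.count_nonzero(ts.au25[sl])) / n,
    )


def detect(
    ts: AUTimeSeries,
    config: DetectionConfig = DetectionConfig(),
    start_frame: Optional[int] = None,
    end_frame: Optional[int] = None,
) -> list[SmileEpisode]:
    """Detect all smile episodes in a session, or in a frame window.

    ``start_frame``/``end_frame`` (inclusive) restrict the analysis to a
    portion of the video; episodes truncated by the window edges are kept.
    Episodes are numbered 1..n in temporal order.
    """
    lo = 0 if start_frame is None else int(start_frame)
    hi = ts.n_frames - 1 if end_frame is None else int(end_frame)
    if lo < 0 or hi >= ts.n_frames or hi < lo:
        raise DataError(
            f"analysis window ({lo},{hi}) outside series of {ts.n_frames} frames"
        )
    smile = classify_frames(ts, config)
    windowed = np.zeros_like(smile)
    windowed[lo : hi + 1] = smile[lo : hi + 1]
    spans = segment_episodes(windowed, ts.fps, config.standby)
    return [episode_metrics(ts, span, index=i + 1) for i, span in enumerate(spans)]


def summarize_session(
    episodes: Sequence[SmileEpisode], session_length: float
) -> SessionSummary:
    """Aggregate episode metrics into a session summary.

    ``relative_smile_time`` is 100 x (summed episode durations) / session
    length; per-episode means are unweighted.
    """
    if session_length <= 0:
        raise DataError("session length must be positive")
    n = len(episodes)
    total = sum(e.duration for e in episodes)
    return SessionSummary(
        n_episodes=n,
        episodes_per_minute=n / (session_length / 60.0),
        mean_duration=(total / n) if n else None,
        relative_smile_time=100.0 * total / session_length,
        mean_au6=(sum(e.mean_au6 for e in episodes) / n) if n else None,
        mean_au12=(sum(e.mean_au12 for e in episodes) / n) if n else None,
        mean_tooth_show=(sum(e.tooth_show for e in episodes) / n) if n else None,
    )


def episodes_to_frame(episodes: Sequence[SmileEpisode], session_id: str) -> pd.DataFrame:
    """Tabulate episodes in the episode-CSV column layout."""
    return pd.DataFrame(
        {
            "session_id": [session_id] * len(episodes),
            "index": [e.index for e in episodes],
            "onset_frame": [e.onset_frame for e in episodes],
            "offset_frame": [e.offset_frame for e in episodes],
            "onset_time_s": [e.onset_time for e in episodes],
            "duration_s": [e.duration for e in episodes],
            "mean_au6": [e.mean_au6 for e in episodes],
            "mean_au12": [e.mean_au12 for e in episodes],
            "tooth_show_pct": [e.tooth_show for e in episodes],
        }
    )
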