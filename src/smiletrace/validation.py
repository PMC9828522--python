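"""Episode-level agreement with manual coding, and confounder analysis.

Two complementary checks of the calibrated detector:

* :func:`match_episodes` — one-to-one matching of detected episodes to
  manually coded reference episodes by temporal overlap, yielding the
  episode-level true-positive rate (matched reference episodes / reference
  episodes).
* :func:`confound_fp_rate` — the fraction of scheduled confounder tasks
  (speaking, yawning, coughing, mouth covering, posed non-smile
  expressions) overlapped by at least one detected episode.  Posed-smiling
  tasks are excluded, since a smile detected there is a correct detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotations import AnnotationTrack, TaskEvent
from .detector import SmileEpisode


@dataclass(frozen=True)
class EpisodeMatchReport:
    """Episode-level agreement between detector and reference coding."""

    n_reference: int
    n_detected: int
    n_matched: int
    true_positive_rate: Optional[float]  # percent; None when no reference
    unmatched_detected: int

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
            "true_positive_rate_pct": self.true_positive_rate,
            "unmatched_detected": self.unmatched_detected,
        }


@dataclass(frozen=True)
class ConfoundReport:
    """False-positive analysis over scheduled confounder tasks."""

    n_tasks: int
    n_flagged: int
    false_positive_rate: Optional[float]  # percent; None when no tasks
    flagged_tasks: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_tasks": self.n_tasks,
            "n_flagged": self.n_flagged,
            "false_positive_rate_pct": self.false_positive_rate,
            "flagged_tasks": list(self.flagged_tasks),
        }


def _overlap_frames(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Frame count of the intersection of two inclusive spans."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def match_episodes(
    detected: Sequence[SmileEpisode],
    reference: AnnotationTrack,
    min_overlap_fraction: float = 0.0,
) -> EpisodeMatchReport:
    """Greedily match detected episodes to reference episodes.

    Candidate pairs must overlap by at least one frame and, when
    ``min_overlap_fraction`` > 0, by at least that fraction of the shorter
    span.  Pairs are matched one-to-one in decreasing overlap order (ties
    by earlier reference, then earlier detection).  The episode-level true
    positive rate is 100 x matched reference / total reference episodes.
    """
    det_spans = [(e.onset_frame, e.offset_frame) for e in detected]
    ref_spans = [(iv.onset_frame, iv.offset_frame) for iv in reference]

    candidates = []
    for ri, rs in enumerate(ref_spans):
        for di, ds in enumerate(det_spans):
            ov = _overlap_frames(rs, ds)
            if ov < 1:
                continue
            shorter = min(rs[1] - rs[0] + 1, ds[1] - ds[0] + 1)
            if ov / shorter >= min_overlap_fraction:
                candidates.append((ov, ri, di))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    used_ref: set[int] = set()
    used_det: set[int] = set()
    for ov, ri, di in candidates:
        if ri in used_ref or di in used_det:
            continue
        used_ref.add(ri)
        used_det.add(di)

    n_ref, n_det, n_match = len(ref_spans), len(det_spans), len(used_ref)
    return EpisodeMatchReport(
        n_reference=n_ref,
        n_detected=n_det,
        n_matched=n_match,
        true_positive_rate=(100.0 * n_match / n_ref) if n_ref else None,
        unmatched_detected=n_det - n_match,
    )


def confound_fp_rate(
    detected: Sequence[SmileEpisode],
    tasks: Sequence[TaskEvent],
    fps: float,
) -> ConfoundReport:
    """Fraction of confounder tasks misdetected as smiles.

    Tasks named ``smiling`` are excluded.  A task is flagged iff any
    detected episode's time span ``[onset, onset + duration)`` intersects
    the task window ``[start, end)``.
    """
    included = [t for t in tasks if t.name != "smiling"]
    ep_spans = [(e.onset_time, e.onset_time + e.duration) for e in detected]
    flagged = [
        t.name
        for t in included
        if any(s < t.end and t.start < e for s, e in ep_spans)
    ]
    n = len(included)
    return ConfoundReport(
        n_tasks=n,
        n_flagged=len(flagged),
        false_positive_rate=(100.0 * len(flagged) / n) if n else None,
        flagged_tasks=tuple(flagged),
    )
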