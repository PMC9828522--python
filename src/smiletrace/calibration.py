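"""Frame-wise calibration of the dual-threshold classifier.

The detector's two thresholds (Th1 on AU6, Th2 on AU12) are calibrated
against manual frame-wise coding: both thresholds are swept over an
inclusive 0.05-step lattice on [0, 5], a pooled confusion table is formed at
every lattice point, and the operating point is chosen by maximising the
Youden index (Se + Sp - 1).  Because the classifier has two free
thresholds, the (FPR, TPR) cloud over the lattice is not a curve; the ROC
is taken as its Pareto upper-left envelope and the AUC as the trapezoidal
area under that envelope.

Classification here is raw frame classification — no stand-by merging —
since calibration precedes episode logic.

``ThresholdCalibration`` is a small model-style front end: construct it
from (series, annotation) pairs, call :meth:`~ThresholdCalibration.fit`,
and read estimates and diagnostics off the returned
:class:`CalibrationResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationTrack, frame_labels
from .detector import classify_frames, DetectionConfig
from .errors import DataError
from .io_openface import AUTimeSeries


class GridPoint(NamedTuple):
    """Confusion counts and derived rates at one (th1, th2) lattice point.

    ``sensitivity``/``specificity``/``youden`` are NaN when undefined
    (no positive, respectively no negative, reference frames).
    """

    th1: float
    th2: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    youden: float
    accuracy: float

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity


def framewise_confusion(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    """Standard 2x2 confusion counts (tp, fp, tn, fn) over frames."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise DataError(f"length mismatch: pred {pred.shape} vs ref {ref.shape}")
    tp = int(np.count_nonzero(pred & ref))
    fp = int(np.count_nonzero(pred & ~ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    return tp, fp, tn, fn


def _lattice(step: float, th_range: tuple[float, float]) -> np.ndarray:
    lo, hi = th_range
    n = int(round((hi - lo) / step))
    # round away accumulated binary noise so lattice values print cleanly
    return np.round(lo + step * np.arange(n + 1), 10)


def threshold_grid(
    sessions: Sequence[tuple[AUTimeSeries, AnnotationTrack]],
    step: float = 0.05,
    th_range: tuple[float, float] = (0.0, 5.0),
) -> list[GridPoint]:
    """Pooled confusion table at every (th1, th2) lattice point.

    Frames from all sessions are pooled into a single table per point.
    Classification uses strict inequalities (au > th) and treats untracked
    frames as negative, exactly as the detector does.

    Implementation: frames are binned once against the threshold lattice
    and per-point counts are recovered by a reverse 2-D cumulative sum, so
    the cost is O(frames + lattice) rather than O(frames x lattice).
    """
    if len(sessions) == 0:
        raise DataError("at least one (series, annotations) session is required")
    if step <= 0:
        raise DataError("threshold step must be positive")
    grid1 = _lattice(step, th_range)
    grid2 = _lattice(step, th_range)

    au6_parts, au12_parts, ref_parts = [], [], []
    for ts, track in sessions:
        labels = frame_labels(track, ts.n_frames)
        valid = ts.valid_mask()
        # untracked frames classify negative at any threshold: push below range
        au6_parts.append(np.where(valid, ts.au6, -np.inf))
        au12_parts.append(np.where(valid, ts.au12, -np.inf))
        ref_parts.append(labels)
    au6 = np.concatenate(au6_parts)
    au12 = np.concatenate(au12_parts)
    ref = np.concatenate(ref_parts)

    # i6[k] = number of lattice values strictly below au6[k]; the frame is
    # "above th1=grid1[a]" iff a < i6[k]
    i6 = np.searchsorted(grid1, au6, side="left")
    i12 = np.searchsorted(grid2, au12, side="left")
    n1, n2 = len(grid1), len(grid2)

    def above_counts(mask: np.ndarray) -> np.ndarray:
        h = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
        np.add.at(h, (i6[mask], i12[mask]), 1)
        # suffix sum over bins with index > a and > b
        s = np.cumsum(np.cumsum(h[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
        return s[1:, 1:]

    n_pos = int(np.count_nonzero(ref))
    n_neg = int(ref.size - n_pos)
    tp = above_counts(ref)
    fp = above_counts(~ref)
    fn = n_pos - tp
    tn = n_neg - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(n_pos > 0, tp / max(n_pos, 1), np.nan)
        sp = np.where(n_neg > 0, tn / max(n_neg, 1), np.nan)
    total = ref.size
    acc = (tp + tn) / total

    points: list[GridPoint] = []
    for a in range(n1):
        for b in range(n2):
            points.append(
                GridPoint(
                    th1=float(grid1[a]),
                    th2=float(grid2[b]),
                    tp=int(tp[a, b]),
                    fp=int(fp[a, b]),
                    tn=int(tn[a, b]),
                    fn=int(fn[a, b]),
                    sensitivity=float(se[a, b]),
                    specificity=float(sp[a, b]),
                    youden=float(se[a, b] + sp[a, b] - 1.0),
                    accuracy=float(acc[a, b]),
                )
            )
    return points


def roc_frontier(grid: Sequence[GridPoint]) -> list[tuple[float, float]]:
    """Pareto upper-left envelope of the grid's (FPR, TPR) cloud.

    For each achieved FPR the maximal TPR is kept, dominated points are
    dropped, and (0,0)/(1,1) are prepended/appended.  The result is
    monotone non-decreasing in both coordinates.
    """
    if len(grid) == 0:
        raise DataError("empty grid")
    pts = [
        (p.fpr, p.sensitivity)
        for p in grid
        if not (math.isnan(p.fpr) or math.isnan(p.sensitivity))
    ]
    frontier: list[tuple[float, float]] = [(0.0, 0.0)]
    best_tpr = 0.0
    for fpr, tpr in sorted(pts, key=lambda q: (q[0], -q[1])):
        if tpr > best_tpr and fpr >= frontier[-1][0]:
            if fpr == frontier[-1][0] and frontier[-1] != (0.0, 0.0):
                frontier[-1] = (fpr, tpr)
            else:
                frontier.append((fpr, tpr))
            best_tpr = tpr
    if frontier[-1] != (1.0, 1.0):
        frontier.append((1.0, 1.0))
    return frontier


def auc(frontier: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a monotone (FPR, TPR) frontier."""
    fpr = np.array([p[0] for p in frontier])
    tpr = np.array([p[1] for p in frontier])
    if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
        raise DataError("frontier must be monotone non-decreasing")
    return float(np.trapezoid(tpr, fpr))


def youden_optimal(grid: Sequence[GridPoint]) -> GridPoint:
    """Lattice point maximising the Youden index Se + Sp - 1.

    Ties are broken in favour of higher specificity, then higher th1, then
    higher th2 (i.e. the most conservative of the tied operating points).
    """
    defined = [p for p in grid if not math.isnan(p.youden)]
    if not defined:
        raise DataError("Youden index undefined at every grid point")
    return max(defined, key=lambda p: (p.youden, p.specificity, p.th1, p.th2))


def grid_to_frame(grid: Sequence[GridPoint]) -> pd.DataFrame:
    """Tabulate a grid in the calibration-report column layout."""
    df = pd.DataFrame(grid)
    return df.rename(columns={"sensitivity": "se", "specificity": "sp"})


@dataclass
class CalibrationResult:
    """Fitted calibration: the full grid, the ROC envelope and the optimum."""

    grid: list[GridPoint]
    frontier: list[tuple[float, float]]
    auc: float
    best: GridPoint
    step: float = 0.05

    @property
    def thresholds(self) -> DetectionConfig:
        """The Youden-optimal operating point as a detector configuration."""
        return DetectionConfig(th1=self.best.th1, th2=self.best.th2)

    def summary(self) -> str:
        b = self.best
        lines = [
            "Dual-threshold smile classifier calibration",
            "=" * 47,
            f"Grid: {len(self.grid)} points, step {self.step:g}",
            f"AUC (Pareto frontier, trapezoid): {self.auc:.3f}",
            f"Youden-optimal thresholds: Th1 (AU6) = {b.th1:.2f}, Th2 (AU12) = {b.th2:.2f}",
            f"  Sensitivity : {100 * b.sensitivity:.1f}%",
            f"  Specificity : {100 * b.specificity:.1f}%",
            f"  Youden J    : {b.youden:.3f}",
            f"  Accuracy    : {100 * b.accuracy:.1f}%",
            f"  Confusion   : tp={b.tp} fp={b.fp} tn={b.tn} fn={b.fn}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "best_th1": self.best.th1,
            "best_th2": self.best.th2,
            "sensitivity": self.best.sensitivity,
            "specificity": self.best.specificity,
            "youden": self.best.youden,
            "accuracy": self.best.accuracy,
        }


@dataclass
class ThresholdCalibration:
    """Calibrate detector thresholds against manual frame-wise coding.

    Parameters
    ----------
    sessions : sequence of (AUTimeSeries, AnnotationTrack)
        Paired series and reference annotations; frames are pooled.
    step : float
        Lattice step for both thresholds (default 0.05).
    th_range : (float, float)
        Inclusive threshold range (default the full 0-5 intensity scale).
    """

    sessions: Sequence[tuple[AUTimeSeries, AnnotationTrack]]
    step: float = 0.05
    th_range: tuple[float, float] = (0.0, 5.0)

    def fit(self) -> CalibrationResult:
        grid = threshold_grid(self.sessions, step=self.step, th_range=self.th_range)
        frontier = roc_frontier(grid)
        return CalibrationResult(
            grid=grid,
            frontier=frontier,
            auc=auc(frontier),
            best=youden_optimal(grid),
            step=self.step,
        )


def predict_labels(
    ts: AUTimeSeries, config: DetectionConfig = DetectionConfig()
) -> np.ndarray:
    """Raw frame classification used in calibration (no episode merging)."""
    return classify_frames(ts, config)
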