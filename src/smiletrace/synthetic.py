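"""Synthetic recording sessions with known ground truth.

The generator emulates the observational setup the detector is meant for: a
participant watches an amusing stimulus video (default 264 s at 30 fps) and
smiles spontaneously now and then, then optionally performs a scripted
sequence of post-video confounder tasks (speaking, yawning, coughing, mouth
covering, posed expressions; posed smiling repeated three times; the
speaking task lasts 10 s, all others 6 s, with 6 s inter-task intervals).

Smile episodes are trapezoidal excursions of AU6 and AU12 above their
generative boundaries — a linear onset ramp, a plateau at the apex, a
linear offset ramp — on top of a constant sub-boundary baseline, with
additive Gaussian noise and a Bernoulli tooth-show (AU25) flag on smile
frames.  Episode count is Poisson in the session length, durations are
log-normal, and placements are rejection-sampled so that ground-truth
episodes respect the two-second smile-free separation rule used by manual
coders.

Default rates, durations, apex intensities and the tooth-show probability
mirror the descriptive statistics of the reference validation sample
(1.6 episodes/min, mean duration 11.3 s ± 5.6, AU6 1.3, AU12 2.2, tooth
show 47.2%); the generative boundaries default to the calibrated operating
thresholds (AU6 0.5, AU12 1.5).

Everything is deterministic in the seed: the same configuration reproduces
a bit-identical session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import (
    AnnotationTrack,
    ReferenceInterval,
    TaskEvent,
    write_annotations,
    write_task_schedule,
)
from .detector import SessionSummary
from .errors import ConfigError
from .io_openface import AUTimeSeries, write_au_csv

#: Post-video task sequence: every task once, posed smiling three times.
TASK_SEQUENCE: tuple[str, ...] = (
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
    "smiling",
    "smiling",
    "neutral",
)
SPEAKING_DURATION = 10.0
TASK_DURATION = 6.0
INTER_TASK_INTERVAL = 6.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative specification of one simulated session.

    seed : RNG seed; identical configs are bit-reproducible.
    fps : camera frame rate (frames/s).
    session_length : stimulus-video length in seconds.
    episode_rate : expected spontaneous smiles per minute.
    duration_mean, duration_sd : episode duration law (log-normal), seconds.
    au6_boundary, au12_boundary : generative separation boundaries on the
        0-5 intensity scale; noise-free trajectories exceed them exactly
        inside ground-truth episodes.
    au6_apex, au12_apex : plateau intensities of the trapezoids.
    ramp : onset/offset ramp length, seconds.
    noise_sd : additive Gaussian noise, intensity units.
    tooth_show_prob : probability a smile frame shows teeth (AU25).
    partial_event_rate : expected partial activations per minute —
        non-Duchenne events (AU12 supra-boundary while AU6 only reaches its
        boundary) alternating with cheek-raise-only events (the mirror
        image).  They contribute no ground-truth smiles but populate the
        near-boundary region of each AU's non-smile intensity distribution,
        which is what makes both thresholds identifiable to a frame-wise
        calibration.
    tasks : append the post-video confounder-task block.
    """

    seed: int = 0
    fps: float = 30.0
    session_length: float = 264.0
    episode_rate: float = 1.6
    duration_mean: float = 11.3
    duration_sd: float = 5.6
    au6_boundary: float = 0.5
    au12_boundary: float = 1.5
    au6_apex: float = 1.3
    au12_apex: float = 2.2
    ramp: float = 0.5
    noise_sd: float = 0.1
    tooth_show_prob: float = 0.472
    partial_event_rate: float = 3.0
    tasks: bool = False
    session_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.session_length <= 0:
            raise ConfigError("fps and session_length must be positive")
        if self.episode_rate < 0 or self.duration_mean <= 0 or self.duration_sd < 0:
            raise ConfigError("rates and durations must be positive")
        for b, a, name in (
            (self.au6_boundary, self.au6_apex, "AU6"),
            (self.au12_boundary, self.au12_apex, "AU12"),
        ):
            if not (0 <= b <= 5):
                raise ConfigError(f"{name} boundary must lie in [0, 5]")
            if not a > b:
                raise ConfigError(f"{name} apex must exceed its boundary")
            if a > 5:
                raise ConfigError(f"{name} apex exceeds the 0-5 scale")
        if not 0 <= self.tooth_show_prob <= 1:
            raise ConfigError("tooth_show_prob must be a probability")
        if self.noise_sd < 0 or self.ramp <= 0:
            raise ConfigError("noise_sd must be >= 0 and ramp > 0")
        if self.partial_event_rate < 0:
            raise ConfigError("partial_event_rate must be >= 0")


@dataclass
class SyntheticSession:
    """A simulated session: series, ground truth, tasks and the config echo."""

    series: AUTimeSeries
    truth: AnnotationTrack
    tasks: list[TaskEvent]
    config: SyntheticConfig = field(repr=False)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _place_episodes(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> list[tuple[float, float]]:
    """Sample (onset_s, duration_s) pairs with >= 2 s + 2 frame separation.

    Spacing construction: draw the duration set, verify it fits with the
    mandatory separations, then spread the remaining free time uniformly
    over the n + 1 gaps.  A configuration whose *expected* smile occupancy
    (rate x (mean duration + separation)) exceeds the session is rejected
    outright; an individual count draw that cannot fit is truncated — a
    saturated session holds as many episodes as physically fit.
    """
    sep = 2.0 + 2.0 / cfg.fps
    expected_occupancy = cfg.episode_rate / 60.0 * (cfg.duration_mean + sep)
    if expected_occupancy > 1.0:
        raise ConfigError(
            "episode_rate x (duration_mean + 2 s separation) exceeds the "
            "session length; the configuration is infeasible"
        )
    n = int(rng.poisson(cfg.episode_rate * cfg.session_length / 60.0))
    mu, sigma = _lognormal_params(cfg.duration_mean, cfg.duration_sd)
    min_dur = 2.0 * cfg.ramp + 2.0 / cfg.fps  # ensure a plateau exists
    slack = 0.0
    durs = np.empty(0)
    while n > 0:
        for _attempt in range(100):
            durs = np.maximum(rng.lognormal(mu, sigma, n), min_dur)
            slack = cfg.session_length - float(durs.sum()) - (n - 1) * sep
            if slack >= 0:
                break
        else:
            n -= 1  # saturated draw: drop one episode and retry
            continue
        break
    if n == 0:
        return []
    cuts = np.sort(rng.uniform(0.0, slack, n))
    gaps = np.diff(np.concatenate(([0.0], cuts, [slack])))
    placed: list[tuple[float, float]] = []
    pos = 0.0
    for i in range(n):
        pos += float(gaps[i])
        placed.append((pos, float(durs[i])))
        pos += float(durs[i]) + sep
    return placed


def _place_partial_events(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    smiles: list[tuple[float, float]],
) -> list[tuple[float, float, str]]:
    """Sample (onset_s, duration_s, active_au) for partial activations.

    Events alternate between AU12-only (non-Duchenne) and AU6-only kinds
    and are kept clear of smile episodes by a 1 s margin.  Events that
    cannot be placed are dropped; partial activity is best-effort colour,
    not ground truth.
    """
    n = int(rng.poisson(cfg.partial_event_rate * cfg.session_length / 60.0))
    margin = 1.0
    blocked = [(o - margin, o + d + margin) for o, d in smiles]
    events: list[tuple[float, float, str]] = []
    for i in range(n):
        active = "au12" if i % 2 == 0 else "au6"
        for _attempt in range(100):
            dur = float(rng.uniform(2.0, 4.0))
            if dur >= cfg.session_length:
                break
            onset = float(rng.uniform(0.0, cfg.session_length - dur))
            if all(onset + dur + margin <= lo or hi + margin <= onset
                   for lo, hi in blocked):
                events.append((onset, dur, active))
                blocked.append((onset, onset + dur))
                break
    return events


def _trapezoid(t: np.ndarray, onset: float, dur: float, ramp: float,
               base: float, apex: float) -> np.ndarray:
    """Trapezoidal excursion from base to apex over [onset, onset + dur]."""
    r = min(ramp, dur / 2.0)
    shape = np.interp(
        t, [onset, onset + r, onset + dur - r, onset + dur], [0.0, 1.0, 1.0, 0.0],
        left=0.0, right=0.0,
    )
    return base + (apex - base) * shape


def _smile_trajectory(t: np.ndarray, onset: float, dur: float, ramp: float,
                      base: float, boundary: float, apex: float) -> np.ndarray:
    """Trapezoid whose boundary crossings fall exactly at onset and offset.

    The linear ramp (base -> apex over ``ramp`` seconds) is shifted so the
    trajectory crosses ``boundary`` at ``onset`` on the way up and at
    ``onset + dur`` on the way down.  Both AUs therefore cross their
    respective boundaries simultaneously, which makes [onset, onset + dur]
    the supra-boundary (ground-truth) interval for the joint rule.
    """
    lead = ramp * (boundary - base) / (apex - base)
    r = min(ramp, (dur + 2 * lead) / 2.0)
    lo, hi = onset - lead, onset + dur + lead
    shape = np.interp(t, [lo, lo + r, hi - r, hi], [0.0, 1.0, 1.0, 0.0],
                      left=0.0, right=0.0)
    return base + (apex - base) * shape


def _boundary_touch(t: np.ndarray, center: float, ramp: float, base: float,
                    boundary: float, apex: float) -> np.ndarray:
    """Triangle that rises to the boundary — never above — and falls back.

    The slope matches the smile ramp's slope at its boundary crossing, so
    the near-boundary intensity density below the boundary mirrors the one
    genuine smiles put just above it.
    """
    lead = ramp * (boundary - base) / (apex - base)
    shape = np.interp(t, [center - lead, center, center + lead], [0.0, 1.0, 0.0],
                      left=0.0, right=0.0)
    return base + (boundary - base) * shape


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def build_task_schedule(cfg: SyntheticConfig) -> list[TaskEvent]:
    """The post-video task block, starting right after the stimulus video."""
    events: list[TaskEvent] = []
    t = cfg.session_length
    for name in TASK_SEQUENCE:
        dur = SPEAKING_DURATION if name == "speaking" else TASK_DURATION
        events.append(TaskEvent(name, t, t + dur))
        t += dur + INTER_TASK_INTERVAL
    return events


def simulate_session(config: SyntheticConfig) -> SyntheticSession:
    """Generate one session with known ground truth.

    The noise-free AU6/AU12 trajectories exceed their boundaries exactly on
    ground-truth frames, so a detector run at the generative boundaries on
    a noise-free session recovers the truth intervals exactly.

    Raises
    ------
    ConfigError
        When the requested episode rate cannot be placed under the 2 s
        separation constraint.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    tasks = build_task_schedule(cfg) if cfg.tasks else []
    total_length = (tasks[-1].end + INTER_TASK_INTERVAL) if tasks else cfg.session_length
    n_frames = int(round(total_length * cfg.fps))
    t = np.arange(n_frames, dtype=float) / cfg.fps

    base6 = float(rng.uniform(0.0, 0.6 * cfg.au6_boundary))
    base12 = float(rng.uniform(0.0, 0.6 * cfg.au12_boundary))
    au6 = np.full(n_frames, base6)
    au12 = np.full(n_frames, base12)

    smiles = _place_episodes(rng, cfg)
    for onset, dur in smiles:
        au6 = np.maximum(
            au6,
            _smile_trajectory(t, onset, dur, cfg.ramp, base6,
                              cfg.au6_boundary, cfg.au6_apex),
        )
        au12 = np.maximum(
            au12,
            _smile_trajectory(t, onset, dur, cfg.ramp, base12,
                              cfg.au12_boundary, cfg.au12_apex),
        )

    for onset, dur, active in _place_partial_events(rng, cfg, smiles):
        center = onset + dur / 2.0
        if active == "au12":
            # non-Duchenne activity: full lip-corner pull, cheek raiser
            # only brushes its boundary from below
            au12 = np.maximum(
                au12,
                _smile_trajectory(t, onset, dur, cfg.ramp, base12,
                                  cfg.au12_boundary, cfg.au12_apex),
            )
            au6 = np.maximum(
                au6,
                _boundary_touch(t, center, cfg.ramp, base6,
                                cfg.au6_boundary, cfg.au6_apex),
            )
        else:
            au6 = np.maximum(
                au6,
                _smile_trajectory(t, onset, dur, cfg.ramp, base6,
                                  cfg.au6_boundary, cfg.au6_apex),
            )
            au12 = np.maximum(
                au12,
                _boundary_touch(t, center, cfg.ramp, base12,
                                cfg.au12_boundary, cfg.au12_apex),
            )

    for ev in tasks:
        pad = 1.0  # active portion sits inside the task window
        start, dur = ev.start + pad, (ev.end - ev.start) - 2 * pad
        if ev.name in ("yawning", "mouth_covering"):
            # jaw movements pull the lip corners (AU12) without the Duchenne
            # marker; stylised, not a claim about facial physiology
            au12 = np.maximum(
                au12, _trapezoid(t, start, dur, cfg.ramp, base12, cfg.au12_apex)
            )
        elif ev.name == "smiling":
            au6 = np.maximum(
                au6, _trapezoid(t, start, dur, cfg.ramp, base6, cfg.au6_apex)
            )
            au12 = np.maximum(
                au12, _trapezoid(t, start, dur, cfg.ramp, base12, cfg.au12_apex)
            )
        elif ev.name != "neutral":
            # sub-boundary perturbation of AU12 only
            au12 = np.maximum(
                au12,
                _trapezoid(t, start, dur, cfg.ramp, base12, 0.8 * cfg.au12_boundary),
            )

    truth_mask = (au6 > cfg.au6_boundary) & (au12 > cfg.au12_boundary)
    truth = AnnotationTrack(
        session_id=cfg.session_id,
        intervals=[ReferenceInterval(s, e) for s, e in _runs(truth_mask)],
    )

    if cfg.noise_sd > 0:
        au6 = au6 + rng.normal(0.0, cfg.noise_sd, n_frames)
        au12 = au12 + rng.normal(0.0, cfg.noise_sd, n_frames)
    au6 = np.clip(au6, 0.0, 5.0)
    au12 = np.clip(au12, 0.0, 5.0)

    au25 = np.zeros(n_frames, dtype=bool)
    au25[truth_mask] = rng.random(int(truth_mask.sum())) < cfg.tooth_show_prob

    series = AUTimeSeries(
        session_id=cfg.session_id,
        frame_index=np.arange(n_frames, dtype=np.int64),
        timestamp=t,
        confidence=np.full(n_frames, 0.98),
        success=np.ones(n_frames, dtype=bool),
        au6=au6,
        au12=au12,
        au25=au25,
        fps=cfg.fps,
    )
    return SyntheticSession(series=series, truth=truth, tasks=tasks, config=cfg)


def simulate_batch(config: SyntheticConfig, n_sessions: int) -> list[SyntheticSession]:
    """Simulate ``n_sessions`` independent sessions, seeds derived from config."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_sessions) % (2**31)
    return [
        simulate_session(
            replace(config, seed=int(s), session_id=f"{config.session_id}-{i:03d}")
        )
        for i, s in enumerate(seeds)
    ]


def expected_session_summary(config: SyntheticConfig) -> SessionSummary:
    """Analytic expectations implied by a configuration.

    Episode-mean AU intensities depend on the trapezoid geometry and are
    not reported here (returned as None); rate, duration, relative smile
    time and tooth show follow directly from the configured laws.
    """
    rate = config.episode_rate
    rst = min(100.0, rate * config.duration_mean / 60.0 * 100.0)
    return SessionSummary(
        n_episodes=int(round(rate * config.session_length / 60.0)),
        episodes_per_minute=rate,
        mean_duration=config.duration_mean if rate > 0 else None,
        relative_smile_time=rst if rate > 0 else 0.0,
        mean_au6=None,
        mean_au12=None,
        mean_tooth_show=100.0 * config.tooth_show_prob if rate > 0 else None,
    )


def write_session(session: SyntheticSession, outdir: str | Path) -> dict[str, Path]:
    """Write the AU CSV, annotation CSV and task CSV for one session."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = session.series.session_id
    paths = {
        "au": outdir / f"{sid}_au.csv",
        "annotations": outdir / f"{sid}_annotations.csv",
        "tasks": outdir / f"{sid}_tasks.csv",
    }
    write_au_csv(session.series, str(paths["au"]))
    write_annotations(session.truth, str(paths["annotations"]))
    write_task_schedule(session.tasks, str(paths["tasks"]))
    return paths
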