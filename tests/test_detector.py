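import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from smiletrace import (
    DataError,
    DetectionConfig,
    classify_frames,
    detect,
    episode_metrics,
    segment_episodes,
    summarize_session,
)


def brute_force_segments(smile, fps, standby):
    """Independent oracle: enumerate runs, then merge by exhaustive gap inspection."""
    runs = []
    i = 0
    n = len(smile)
    while i < n:
        if smile[i]:
            j = i
            while j + 1 < n and smile[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) / fps < standby:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


class TestClassifyFrames:
    @pytest.mark.parametrize(
        "au6,au12,expected",
        [
            (0.6, 2.0, True),   # both above
            (0.6, 1.0, False),  # AU12 below
            (0.4, 2.0, False),  # AU6 below
            (0.5, 1.5, False),  # exactly at threshold: strict inequality
        ],
    )
    def test_joint_strict_rule(self, make_series, au6, au12, expected):
        ts = make_series([au6], [au12])
        assert classify_frames(ts, DetectionConfig(0.5, 1.5)).tolist() == [expected]

    def test_untracked_frame_is_never_a_smile(self, make_series):
        ts = make_series([2.0, 2.0], [3.0, 3.0], success=[True, False])
        assert classify_frames(ts).tolist() == [True, False]


class TestSegmentEpisodes:
    def test_short_gap_merges(self):
        smile = [False, True, True, False, True, True, False]
        assert segment_episodes(np.array(smile), fps=1.0, standby=2.0) == [(1, 5)]

    def test_gap_equal_to_standby_splits(self):
        smile = [True, True, False, False, True, True]
        assert segment_episodes(np.array(smile), fps=1.0, standby=2.0) == [(0, 1), (4, 5)]

    def test_all_false_yields_nothing(self):
        assert segment_episodes(np.zeros(10, dtype=bool), fps=30.0) == []

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 51)
            smile = rng.random(n) < rng.uniform(0.1, 0.9)
            fps = float(rng.uniform(1, 60))
            standby = float(rng.uniform(0.05, 3.0))
            got = segment_episodes(smile, fps, standby)
            assert got == brute_force_segments(smile.tolist(), fps, standby)


class TestEpisodeMetrics:
    def test_half_au25_gives_fifty_percent_tooth_show(self, make_series):
        ts = make_series([2.0] * 10, [3.0] * 10, au25=[True] * 5 + [False] * 5, fps=1.0)
        ep = episode_metrics(ts, (0, 9))
        assert ep.tooth_show == 50.0
        assert ep.duration == 10.0

    def test_single_frame_episode(self, make_series):
        ts = make_series([1.0], [2.0], au25=[True], fps=30.0)
        ep = episode_metrics(ts, (0, 0))
        assert ep.mean_au6 == 1.0
        assert ep.mean_au12 == 2.0
        assert ep.tooth_show == 100.0
        assert ep.duration == pytest.approx(1 / 30)

    def test_arithmetic_mean_over_span(self, make_series):
        ts = make_series([1, 1, 2, 2], [2, 2, 2, 2])
        assert episode_metrics(ts, (0, 3)).mean_au6 == 1.5

    def test_span_outside_series_rejected(self, make_series):
        ts = make_series([1.0] * 4, [2.0] * 4)
        with pytest.raises(DataError):
            episode_metrics(ts, (2, 9))


class TestDetect:
    def _three_smile_series(self, make_series, fps=10.0):
        n = 400
        au6 = np.zeros(n)
        au12 = np.zeros(n)
        spans = [(50, 80), (150, 200), (300, 340)]  # gaps >> standby
        for a, b in spans:
            au6[a : b + 1] = 1.0
            au12[a : b + 1] = 2.0
        return make_series(au6, au12, fps=fps), spans

    def test_all_zero_series_has_no_episodes(self, make_series):
        ts = make_series(np.zeros(100), np.zeros(100))
        assert detect(ts) == []

    def test_recovers_three_well_separated_smiles(self, make_series):
        ts, spans = self._three_smile_series(make_series)
        episodes = detect(ts, DetectionConfig(0.5, 1.5))
        assert [(e.onset_frame, e.offset_frame) for e in episodes] == spans
        assert [e.index for e in episodes] == [1, 2, 3]

    def test_window_restricts_to_second_smile(self, make_series):
        ts, spans = self._three_smile_series(make_series)
        episodes = detect(ts, start_frame=120, end_frame=250)
        assert [(e.onset_frame, e.offset_frame) for e in episodes] == [spans[1]]

    def test_window_outside_series_rejected(self, make_series):
        ts = make_series(np.zeros(10), np.zeros(10))
        with pytest.raises(DataError):
            detect(ts, start_frame=5, end_frame=20)

    def test_durations_are_multiples_of_frame_interval(self, make_series, rng):
        ts = make_series(rng.uniform(0, 2, 500), rng.uniform(0, 3, 500), fps=30.0)
        for ep in detect(ts):
            assert (ep.duration * 30.0) == pytest.approx(round(ep.duration * 30.0))
            assert (ep.onset_time * 30.0) == pytest.approx(round(ep.onset_time * 30.0))


class TestSummarize:
    def test_zero_episodes(self):
        s = summarize_session([], 300.0)
        assert s.n_episodes == 0
        assert s.relative_smile_time == 0.0
        assert s.mean_duration is None and s.mean_au6 is None

    def test_episodes_per_minute(self, make_series):
        ts = make_series([2.0] * 10, [3.0] * 10, fps=1.0)
        eps = [episode_metrics(ts, (i, i), index=i + 1) for i in range(8)]
        assert summarize_session(eps, 300.0).episodes_per_minute == pytest.approx(1.6)

    def test_relative_smile_time(self, make_series):
        ts = make_series([2.0] * 91, [3.0] * 91, fps=1.0)
        eps = [episode_metrics(ts, (0, 29)), episode_metrics(ts, (31, 90))]
        assert summarize_session(eps, 300.0).relative_smile_time == pytest.approx(30.0)


class TestMonotonicityProperties:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=hst.lists(
            hst.tuples(hst.floats(0, 5), hst.floats(0, 5)), min_size=1, max_size=60
        ),
        th=hst.tuples(hst.floats(0, 5), hst.floats(0, 5)),
        dth=hst.tuples(hst.floats(0, 1), hst.floats(0, 1)),
    )
    def test_raising_thresholds_shrinks_smile_set(self, data, th, dth):
        from tests_helpers import series_from_pairs  # local helper below

        ts = series_from_pairs(data)
        lo = classify_frames(ts, DetectionConfig(min(th[0], 5), min(th[1], 5)))
        hi = classify_frames(
            ts, DetectionConfig(min(th[0] + dth[0], 5), min(th[1] + dth[1], 5))
        )
        assert np.all(lo | ~hi)  # hi ⊆ lo

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        smile=hst.lists(hst.booleans(), min_size=1, max_size=80),
        standby=hst.floats(0.1, 4.0),
        extra=hst.floats(0.0, 4.0),
    )
    def test_raising_standby_never_adds_episodes(self, smile, standby, extra):
        v = np.array(smile)
        n_lo = len(segment_episodes(v, fps=1.0, standby=standby))
        n_hi = len(segment_episodes(v, fps=1.0, standby=standby + extra))
        assert n_hi <= n_lo

    def test_episode_frames_cover_smile_frames(self, make_series, rng):
        ts = make_series(rng.uniform(0, 2, 400), rng.uniform(0, 3, 400), fps=30.0)
        smile = classify_frames(ts)
        episodes = detect(ts)
        covered = sum(e.n_frames for e in episodes)
        assert covered >= int(smile.sum())
        total = sum(e.duration for e in episodes)
        s = summarize_session(episodes, ts.duration)
        assert s.relative_smile_time == 100.0 * total / ts.duration
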