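import numpy as np
import pytest

from smiletrace import AUTimeSeries


def build_series(au6, au12, au25=None, success=None, fps=30.0, session_id="s1"):
    """Assemble an AUTimeSeries from plain lists, timestamps on the fps grid."""
    au6 = np.asarray(au6, dtype=float)
    n = au6.size
    au12 = np.asarray(au12, dtype=float)
    au25 = np.zeros(n, dtype=bool) if au25 is None else np.asarray(au25, dtype=bool)
    success = (
        np.ones(n, dtype=bool) if success is None else np.asarray(success, dtype=bool)
    )
    return AUTimeSeries(
        session_id=session_id,
        frame_index=np.arange(n, dtype=np.int64),
        timestamp=np.arange(n, dtype=float) / fps,
        confidence=np.full(n, 0.98),
        success=success,
        au6=au6,
        au12=au12,
        au25=au25,
        fps=fps,
    )


@pytest.fixture
def make_series():
    return build_series


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
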