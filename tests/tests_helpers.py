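import numpy as np

from conftest import build_series


def series_from_pairs(pairs, fps=30.0):
    au6 = np.array([p[0] for p in pairs])
    au12 = np.array([p[1] for p in pairs])
    return build_series(au6, au12, fps=fps)
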