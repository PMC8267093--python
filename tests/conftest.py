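import numpy as np
import pytest

from usvkit.synthetic import default_presets


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def match_intervals(truth_iv, det_iv, min_overlap_frac=0.5):
    """Greedy matching of truth to detected intervals by temporal overlap."""
    def overlap(a, b):
        return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))

    matches, used = [], set()
    for i, t in enumerate(truth_iv):
        cand = [(overlap(t, d), j) for j, d in enumerate(det_iv) if j not in used]
        o, bj = max(cand, default=(0.0, None))
        if bj is not None and o >= min_overlap_frac * (t[1] - t[0]):
            matches.append((i, bj))
            used.add(bj)
    return matches
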