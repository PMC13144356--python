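import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from whistlekit.contours import WhistleContour, _local_similarity_matrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def dtw_brute_force(fa, fb, warp_factor):
    """Exhaustive enumeration of admissible warp paths; returns the maximum
    mean local similarity, or None when no admissible path exists.

    Independent of the DP implementation: plain depth-first search over
    monotone paths with at most warp_factor-1 consecutive single-sequence
    steps per direction.
    """
    sim = _local_similarity_matrix(np.asarray(fa, float), np.asarray(fb, float))
    n, m = sim.shape
    W = int(warp_factor)
    best = [None]

    def rec(i, j, last, run, total, length):
        if i == n - 1 and j == m - 1:
            mean = total / length
            if best[0] is None or mean > best[0]:
                best[0] = mean
            return
        if i < n - 1 and j < m - 1:
            rec(i + 1, j + 1, "d", 0, total + sim[i + 1, j + 1], length + 1)
        if W > 1 and j < m - 1 and (last != "h" or run < W - 1):
            rec(i, j + 1, "h", run + 1 if last == "h" else 1,
                total + sim[i, j + 1], length + 1)
        if W > 1 and i < n - 1 and (last != "v" or run < W - 1):
            rec(i + 1, j, "v", run + 1 if last == "v" else 1,
                total + sim[i + 1, j], length + 1)

    rec(0, 0, "", 0, sim[0, 0], 1)
    return best[0]


def bouts_brute_force(onsets, window_s, min_count):
    """All maximal qualifying runs by explicit enumeration of every run."""
    onsets = list(onsets)
    n = len(onsets)
    qualifying = []
    for a in range(n):
        for b in range(a + min_count - 1, n):
            if all(onsets[k + 1] - onsets[k] <= window_s for k in range(a, b)):
                qualifying.append((a, b))
    # keep maximal runs only
    return [
        (a, b)
        for a, b in qualifying
        if not any((c <= a and b <= d and (c, d) != (a, b)) for c, d in qualifying)
    ]


def make_contour(freqs, dt_s=0.005, cid="c1", **kw):
    defaults = dict(recording_id="r1", day_label="day1", onset_s=0.0,
                    snr_class="high")
    defaults.update(kw)
    return WhistleContour(id=cid, dt_s=dt_s, freqs_khz=np.asarray(freqs, float),
                         **defaults)


@pytest.fixture
def flat5():
    return make_contour(np.full(101, 5.0), cid="flat5")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
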