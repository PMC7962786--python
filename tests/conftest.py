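import numpy as np
import pytest

from gazecraft.geometry import DEFAULT_GEOMETRY, ImageFrame, ScreenGeometry
from gazecraft.io import Samples
from gazecraft.maps import KernelSpec


@pytest.fixture
def geom() -> ScreenGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture
def frame(geom) -> ImageFrame:
    return ImageFrame.centered(geom, 1300, 800)


@pytest.fixture
def small_frame(geom) -> ImageFrame:
    """A compact image rectangle for map tests that need dense oracles."""
    return ImageFrame.centered(geom, 320, 240)


@pytest.fixture
def kernel() -> KernelSpec:
    return KernelSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_still_trial(n_ms: int = 500, x: float = 960.0, y: float = 540.0) -> Samples:
    t = np.arange(n_ms, dtype=float)
    return Samples(t, np.full(n_ms, x), np.full(n_ms, y), np.ones(n_ms, dtype=bool))


def minjerk_displacement(n: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def make_saccade_trial(
    amplitude_deg: float = 5.0,
    sacc_dur_ms: int = 40,
    still_ms: int = 300,
    ppd: float = 39.041154024075055,
    n_saccades: int = 1,
    start=(700.0, 540.0),
) -> Samples:
    """Still -> smooth sigmoidal displacement(s) -> still, all valid, 1 kHz."""
    xs = [np.full(still_ms, start[0])]
    ys = [np.full(still_ms, start[1])]
    x0 = start[0]
    for _ in range(n_saccades):
        prof = minjerk_displacement(sacc_dur_ms)
        xs.append(x0 + amplitude_deg * ppd * prof)
        ys.append(np.full(sacc_dur_ms, start[1]))
        x0 += amplitude_deg * ppd
        xs.append(np.full(still_ms, x0))
        ys.append(np.full(still_ms, start[1]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x), dtype=float)
    return Samples(t, x, y, np.ones(len(x), dtype=bool))


def brute_force_saccade_scan(samples: Samples, geom, vel_thresh=30.0, acc_thresh=8000.0, halfwidth=1):
    """Independent threshold scan: plain-python loop over finite differences.

    Mirrors the detection *definition* (moving-average smoothing, central
    differences, OR of thresholds) without sharing any code with the
    detector's run extraction or merging.
    """
    from gazecraft.geometry import px_per_degree

    ppd = px_per_degree(geom, check_isotropy=False)
    n = len(samples)
    w = 2 * halfwidth + 1
    xs, ys = [], []
    for i in range(n):
        lo, hi = max(i - halfwidth, 0), min(i + halfwidth + 1, n)
        block_x = list(samples.x_px[lo:hi])
        block_y = list(samples.y_px[lo:hi])
        while len(block_x) < w:  # edge padding, same as the detector
            if lo == 0:
                block_x.insert(0, samples.x_px[0])
                block_y.insert(0, samples.y_px[0])
            else:
                block_x.append(samples.x_px[-1])
                block_y.append(samples.y_px[-1])
        xs.append(sum(block_x) / w)
        ys.append(sum(block_y) / w)

    t_s = [tm / 1000.0 for tm in samples.t_ms]

    def central(seq, i):
        if i == 0:
            return (seq[1] - seq[0]) / (t_s[1] - t_s[0])
        if i == n - 1:
            return (seq[-1] - seq[-2]) / (t_s[-1] - t_s[-2])
        return (seq[i + 1] - seq[i - 1]) / (t_s[i + 1] - t_s[i - 1])

    vx = [central(xs, i) / ppd for i in range(n)]
    vy = [central(ys, i) / ppd for i in range(n)]
    speed = [np.hypot(a, b) for a, b in zip(vx, vy)]
    ax = [central(vx, i) for i in range(n)]
    ay = [central(vy, i) for i in range(n)]
    acc = [np.hypot(a, b) for a, b in zip(ax, ay)]

    above = [s > vel_thresh or a > acc_thresh for s, a in zip(speed, acc)]
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs
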