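import numpy as np
import pandas as pd
import pytest

from aeroscope import FishPhenotype, SimConfig


@pytest.fixture
def phenotype():
    """A mid-sized fish with round-number physiology for arithmetic checks."""
    return FishPhenotype(
        fish_id="f1", population="coastal", sex="male",
        body_mass=3.5, fork_length=640.0,
        rmr12=2.0, q10_true=2.0, mmr_true=10.0, epoc_rate_k=0.05,
    )


@pytest.fixture
def quiet_config():
    """Noise-free, burst-free protocol config (15-min cycles, 72 overnight)."""
    return SimConfig(noise_sd=0.0, test_temperature=12.0, cycle_count=72, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_mmr_slope(t, o2, min_window_s=90.0, r2_min=0.9):
    """Independent oracle: steepest qualifying slope by naive enumeration.

    Fits every (start, end) sample pair spanning >= min_window_s and >= 5
    points with numpy.polyfit and returns the most negative slope (per
    second) with r^2 > r2_min, or None.
    """
    t = np.asarray(t, float)
    y = np.asarray(o2, float)
    n = len(t)
    best = None
    for i in range(n):
        for j in range(i + 4, n):
            if t[j] - t[i] < min_window_s:
                continue
            tt, yy = t[i:j + 1], y[i:j + 1]
            slope, intercept = np.polyfit(tt, yy, 1)
            resid = yy - (intercept + slope * tt)
            ss_tot = np.sum((yy - yy.mean()) ** 2)
            if ss_tot == 0:
                continue
            r2 = 1.0 - np.sum(resid ** 2) / ss_tot
            if slope < 0 and r2 > r2_min:
                if best is None or slope < best:
                    best = slope
    return best
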