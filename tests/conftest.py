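import numpy as np
import pandas as pd
import pytest

from cyclesense.ingest import RawSegment
from cyclesense.preprocess import UniformSegment


def bruteforce_band_power(y, fs_hz, band, nyquist_closed=False):
    """O(N^2) explicitly-summed DFT oracle for the relative band power."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ks = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(ks, np.arange(n)) / n) @ y
    power = np.abs(dft) ** 2
    fc1, fc2 = band
    # same edge-bin convention as the implementation: fc1 <= k fs / N < fc2
    # decided on the products k*fs vs fc*N
    kfs = ks * fs_hz
    mask = (kfs >= fc1 * n) if nyquist_closed else (kfs >= fc1 * n) & (kfs < fc2 * n)
    return power[mask].sum() / power.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_track(t, alt, dist, speed, hr, lat=49.2, lon=16.6):
    t = np.asarray(t, dtype=float)
    full = lambda v: np.full(t.size, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
    return pd.DataFrame({
        "t_s": t, "lat_deg": full(lat), "lon_deg": full(lon),
        "alt_m": full(alt), "dist_m": full(dist),
        "speed_ms": full(speed), "hr_bpm": full(hr),
    })


def make_raw_segment(t_accel, ax, ay, az, track, position="Spine2", class_id="c1"):
    accel = pd.DataFrame({
        "t_s": np.asarray(t_accel, float),
        "ax_ms2": np.asarray(ax, float),
        "ay_ms2": np.asarray(ay, float),
        "az_ms2": np.asarray(az, float),
    })
    return RawSegment(position=position, class_id=class_id, accel=accel,
                      track=track, segment_id="test")


def make_uniform(modulus, fs_hz=60.0, hr=130.0, slope=10.0, position="Spine2",
                 class_id="c1"):
    return UniformSegment(position=position, class_id=class_id, fs_hz=fs_hz,
                          modulus=np.asarray(modulus, float), hr_mean_bpm=hr,
                          slope_pct=slope, speed_mean_ms=5.0, speed_std_ms=0.1)
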