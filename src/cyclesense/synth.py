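"""Synthetic cycling-segment generator parameterized by the published tables.

The study's recordings are not deposited, so this module generates data
carrying the statistical structure the analysis assumes:

* feature-level samples: independent Gaussians per feature with the
  published per-class means/STDs, band fractions clipped to [0, 1] and
  renormalized to sum to 1;
* raw segments: tri-axial acceleration built as an offset plus a sinusoid
  mixture whose one-sided spectral line weights realize a drawn set of
  band-power targets.  Line frequencies lie strictly inside each band, the
  offset exceeds the mixture's crest so the modulus is nonnegative by
  construction, and a short per-segment calibration measures the band
  fractions through the exact downstream chain (irregular sampling,
  interpolation, FIR, 60 Hz resampling, de-meaned DFT) and adjusts the
  per-band weights so the delivered fractions match the targets;
* tracks: slowly varying heart rate around a drawn per-segment level at the
  0.48 Hz Garmin rate, piecewise-linear altitude consistent with the drawn
  slope, and a configurable fraction of speed-unstable segments for the QC
  stage to reject.

Identical (config, seed) inputs produce byte-identical datasets.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as _feat
from . import preprocess as _pre
from .ingest import ACCEL_COLUMNS, RawSegment
from .profiles import CLASS_IDS, POSITIONS, SEGMENT_COUNTS, ClassProfile, all_profiles

__all__ = [
    "SynthConfig",
    "DatasetPaths",
    "gen_feature_samples",
    "gen_feature_dataset",
    "gen_raw_segment",
    "gen_dataset",
    "default_config",
]

# Spectral-line placement margins inside each analysis band (Hz).  Lines are
# kept away from band edges so DFT leakage cannot cross a boundary.
_LINE_RANGES = ((0.4, 2.75), (3.25, 7.75), (8.3, 14.7), (15.3, 27.0))
_TRACK_RATE_HZ = 0.48


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the emulated acquisition.

    Attributes
    ----------
    positions : tuple of str
        Sensor positions to generate.
    segments_per_class_per_position : int
        Segment count per (position, class) cell when explicit per-position
        counts are not given.
    counts_per_position, rejected_per_position : dict, optional
        Explicit per-position totals and speed-unstable counts (the study's
        bookkeeping).  When given they override the per-cell count and
        ``bad_segment_rate``.
    seed : int
        Master seed; every segment derives its own stream from it.
    fs_mean_hz : float
        Mean accelerometer rate (the study reports 142 Hz).
    fs_jitter : float
        Log-normal sigma of the inter-sample intervals.
    segment_duration_s : float
        Length of each segment (the study does not state one; 60 s default).
    bad_segment_rate : float
        Fraction of speed-unstable segments when explicit rejected counts
        are not given (the study rejected 39/1293 ~ 3%).
    """

    positions: tuple[str, ...] = POSITIONS
    segments_per_class_per_position: int = 1
    counts_per_position: dict[str, int] | None = None
    rejected_per_position: dict[str, int] | None = None
    seed: int = 0
    fs_mean_hz: float = 142.0
    fs_jitter: float = 0.35
    segment_duration_s: float = 60.0
    bad_segment_rate: float = 39.0 / 1293.0
    lines_per_band: int = 10
    preprocess: _pre.PreprocessConfig = field(default_factory=_pre.PreprocessConfig)

    def __post_init__(self) -> None:
        if self.segment_duration_s < 2.0:
            raise ValueError("segment_duration_s must be >= 2 s to resolve <0,3> Hz")
        if not 0.0 <= self.bad_segment_rate < 1.0:
            raise ValueError("bad_segment_rate must lie in [0, 1)")
        if self.segments_per_class_per_position < 1 and self.counts_per_position is None:
            raise ValueError("segment counts must be positive")
        if self.fs_mean_hz <= 0 or self.fs_jitter < 0:
            raise ValueError("invalid sampling-rate model")
        unknown = set(self.positions) - set(POSITIONS)
        if unknown:
            raise ValueError(f"unknown positions {sorted(unknown)}")

    def position_counts(self) -> dict[str, tuple[int, int]]:
        """(total, speed-unstable) per position under this config."""
        out: dict[str, tuple[int, int]] = {}
        for pos in self.positions:
            if self.counts_per_position is not None:
                n = int(self.counts_per_position[pos])
            else:
                n = self.segments_per_class_per_position * len(CLASS_IDS)
            if self.rejected_per_position is not None:
                bad = int(self.rejected_per_position.get(pos, 0))
            else:
                bad = int(round(self.bad_segment_rate * n))
            if bad > n:
                raise ValueError(f"{pos}: more rejected ({bad}) than total ({n})")
            out[pos] = (n, bad)
        return out

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["positions"] = list(self.positions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def default_config(seed: int = 0) -> SynthConfig:
    """The study-sized dataset: 1293 segments, 39 of them speed-unstable."""
    return SynthConfig(
        counts_per_position={p: n for p, (n, _) in SEGMENT_COUNTS.items()},
        rejected_per_position={p: r for p, (_, r) in SEGMENT_COUNTS.items()},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# feature-level generation


def gen_feature_samples(profile: ClassProfile, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` feature vectors (4 band fractions + heart rate) from a profile.

    Band fractions are independent Gaussians clipped to [0, 1] and
    renormalized to sum to 1; the heart rate is an independent Gaussian.
    The same seed always reproduces the same table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bands = rng.normal(profile.band_means, profile.band_stds, size=(n, 4))
    bands = np.clip(bands, 0.0, 1.0)
    sums = bands.sum(axis=1)
    dead = sums <= 0
    if dead.any():  # all four draws clipped to zero: fall back to the means
        bands[dead] = profile.band_means
        sums[dead] = np.sum(profile.band_means)
    bands /= sums[:, None]
    hr = rng.normal(profile.hr_mean_bpm, profile.hr_std_bpm, size=n)
    df = pd.DataFrame(bands, columns=list(_feat.BAND_NAMES))
    df["HR"] = hr
    return df


def expected_feature_moments(profile: ClassProfile) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean and SD of the features :func:`gen_feature_samples` draws.

    The clip-at-zero and simplex renormalization shift the band moments
    slightly away from the raw profile values.  To first order the expected
    band fraction is ``E[max(X_i, 0)] / sum_j E[max(X_j, 0)]`` with
    ``E[max(X, 0)] = mu Phi(mu/sigma) + sigma phi(mu/sigma)``, and the
    delta-method SD of the renormalized fraction is

        sd_i^2 = sigma_i^2 (1 - e_i)^2 + e_i^2 sum_{j != i} sigma_j^2.

    The shift from the table values is small (under 2e-3 absolute for every
    study cell); heart rate is untouched.  Returns 5-vectors ordered as
    :data:`cyclesense.features.FEATURE_NAMES`.
    """
    from scipy.stats import norm

    mu = np.asarray(profile.band_means, dtype=float)
    sd = np.asarray(profile.band_stds, dtype=float)
    with np.errstate(divide="ignore"):
        a = np.where(sd > 0, mu / np.where(sd > 0, sd, 1.0), np.inf)
    clipped_mean = np.where(sd > 0, mu * norm.cdf(a) + sd * norm.pdf(a), mu)
    e = clipped_mean / clipped_mean.sum()
    var_all = np.sum(sd**2)
    sd_eff = np.sqrt(sd**2 * (1.0 - e) ** 2 + e**2 * (var_all - sd**2))
    means = np.concatenate([e, [profile.hr_mean_bpm]])
    sds = np.concatenate([sd_eff, [profile.hr_std_bpm]])
    return means, sds


def gen_feature_dataset(
    n_per_class: int,
    seed: int,
    positions: tuple[str, ...] = POSITIONS,
    profiles: dict[tuple[str, str], ClassProfile] | None = None,
) -> _feat.FeatureMatrix:
    """Feature matrix drawn from the published per-class profiles.

    Convenience wrapper used by the placement and classification studies:
    ``n_per_class`` rows per (position, class) cell, deterministic per seed.
    """
    profiles = profiles or all_profiles()
    blocks, targets, poss = [], [], []
    for i, pos in enumerate(positions):
        for j, cid in enumerate(CLASS_IDS):
            ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0xFEA7, i, j])
            df = gen_feature_samples(profiles[(pos, cid)], n_per_class,
                                     seed=int(ss.generate_state(1)[0] % (2**31)))
            blocks.append(df.to_numpy().T)
            targets.extend([cid] * n_per_class)
            poss.extend([pos] * n_per_class)
    return _feat.FeatureMatrix(
        P=np.concatenate(blocks, axis=1),
        targets=np.array(targets),
        positions=np.array(poss),
    )


# ---------------------------------------------------------------------------
# raw-signal generation


class _SinusoidMixture:
    """Offset + per-band spectral lines with calibrated downstream fractions."""

    def __init__(self, duration: float, lines_per_band: int, rng: np.random.Generator):
        freqs, band_of = [], []
        for b, (lo, hi) in enumerate(_LINE_RANGES):
            grid = np.arange(np.ceil(lo * duration), np.floor(hi * duration) + 1)
            grid = grid / duration  # snap lines to the segment's DFT bin grid
            k = min(lines_per_band, len(grid))
            pick = np.sort(rng.choice(len(grid), size=k, replace=False))
            freqs.append(grid[pick])
            band_of.append(np.full(k, b))
        self.freqs = np.concatenate(freqs)
        self.band_of = np.concatenate(band_of)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, self.freqs.size)
        self.amps = np.zeros(self.freqs.size)
        self.offset = 0.0
        # dense grid only used to measure the mixture's crest
        self._td = np.arange(int(duration * 240)) / 240.0
        self._cos_dense = self._cos_matrix(self._td)
        self._cached_t: np.ndarray | None = None
        self._cos_cached: np.ndarray | None = None

    def _cos_matrix(self, t: np.ndarray) -> np.ndarray:
        return np.cos(2.0 * np.pi * np.outer(t, self.freqs) + self.phases)

    def set_band_weights(self, per_band: np.ndarray) -> None:
        w = np.zeros(self.freqs.size)
        for b in range(4):
            sel = self.band_of == b
            prof = np.linspace(1.0, 0.5, sel.sum())
            w[sel] = per_band[b] * prof / prof.sum()
        self.amps = 2.0 * np.sqrt(w)  # one-sided line weight (a/2)^2 = w
        ac = self._cos_dense @ self.amps
        self.offset = 1.05 * max(-ac.min(), 0.0) + 1e-12

    def __call__(self, t: np.ndarray) -> np.ndarray:
        if self._cached_t is not None and t is self._cached_t:
            cos = self._cos_cached
        else:
            cos = self._cos_matrix(t)
            self._cached_t, self._cos_cached = t, cos
        return np.maximum(self.offset + cos @ self.amps, 0.0)


def _irregular_timestamps(duration: float, fs_mean: float, jitter: float,
                          rng: np.random.Generator) -> np.ndarray:
    mu = np.log(1.0 / fs_mean) - jitter**2 / 2.0  # mean interval = 1/fs_mean
    n_draw = max(int(duration * fs_mean * 1.7), 16)
    dts = np.exp(rng.normal(mu, jitter, n_draw))
    t = np.concatenate([[0.0], np.cumsum(dts)])
    t = t[t <= duration]
    if t.size < 8:
        raise ValueError("segment too short for the sampling model")
    return t


def _chain_band_fractions(t: np.ndarray, x: np.ndarray,
                          pp: _pre.PreprocessConfig) -> np.ndarray:
    """Band fractions after the exact preprocessing chain (single axis)."""
    n1 = t.size
    span = t[-1] - t[0]
    fs1 = (n1 - 1) / span
    _, xu = _pre.resample_uniform(t, x, n1)
    b = _pre.design_lowpass(pp.fir_order, pp.effective_cutoff(fs1), fs1)
    xf = _pre.fir_filter(xu, b)
    tu = np.linspace(t[0], t[-1], n1)
    n2 = max(2, int(round(span * pp.fs_target_hz)) + 1)
    _, x2 = _pre.resample_uniform(tu, xf, n2)
    fs2 = (n2 - 1) / span
    y = np.abs(x2)
    y = y - y.mean()
    spec = _feat.BandSpec()
    return np.array([
        _feat.band_power(y, fs2, bnd, nyquist_closed=(i == 3))
        for i, bnd in enumerate(spec.bands)
    ])


def _design_modulus(targets: np.ndarray, t_local: np.ndarray, duration: float,
                    lines_per_band: int, pp: _pre.PreprocessConfig,
                    rng: np.random.Generator, n_cal: int = 2) -> _SinusoidMixture:
    mix = _SinusoidMixture(duration, lines_per_band, rng)
    work = targets.astype(float).copy()
    for _ in range(n_cal + 1):
        mix.set_band_weights(work)
        meas = _chain_band_fractions(t_local, mix(t_local), pp)
        adj = np.clip(targets / np.maximum(meas, 1e-7), 1.0 / 3.0, 3.0)
        work = np.clip(work * adj, 0.0, None)
        s = work.sum()
        if s > 0:
            work /= s
    mix.set_band_weights(work)
    return mix


def _gen_track(duration: float, t_start: float, profile: ClassProfile,
               rng: np.random.Generator, speed_unstable: bool,
               alt0: float = 250.0, dist0: float = 0.0) -> tuple[pd.DataFrame, float]:
    dt = 1.0 / _TRACK_RATE_HZ
    n = max(2, int(np.floor(duration / dt)))
    tt = np.arange(n) * dt
    v0 = rng.uniform(3.5, 7.0)
    if speed_unstable:
        swing = 0.85 * v0 * (-1.0) ** np.arange(n)
        v = v0 + swing + rng.normal(0.0, 0.05 * v0, n)
    else:
        v = v0 + rng.normal(0.0, 0.04 * v0, n)
    v = np.clip(v, 0.2, None)
    dist = dist0 + np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(tt))])
    slope = rng.normal(profile.slope_mean_pct, profile.slope_std_pct)
    alt = alt0 + slope / 100.0 * (dist - dist0)
    hr_level = float(np.clip(rng.normal(profile.hr_mean_bpm, profile.hr_std_bpm),
                             45.0, 215.0))
    ar = np.empty(n)
    ar[0] = rng.normal(0.0, 1.5)
    for k in range(1, n):  # slowly varying HR fluctuation around the level
        ar[k] = 0.9 * ar[k - 1] + rng.normal(0.0, 1.5 * np.sqrt(1 - 0.81))
    hr = hr_level + ar
    lat = 49.2 + (dist - dist0) / 111320.0
    lon = np.full(n, 16.6)
    df = pd.DataFrame({
        "t_s": t_start + tt,
        "lat_deg": lat,
        "lon_deg": lon,
        "alt_m": alt,
        "dist_m": dist,
        "speed_ms": v,
        "hr_bpm": hr,
    })
    return df, slope


def gen_raw_segment(
    profile: ClassProfile,
    config: SynthConfig,
    seed: int,
    *,
    speed_unstable: bool = False,
    t_start: float = 0.0,
    alt0: float = 250.0,
    dist0: float = 0.0,
    band_targets: np.ndarray | None = None,
) -> RawSegment:
    """Generate one raw segment (irregular tri-axial acceleration + track).

    The acceleration modulus is an offset plus a sinusoid mixture whose
    delivered band-power fractions (through the standard preprocessing and
    de-meaned DFT) match a draw from the profile; the three axes share a
    fixed random direction so the modulus equals the designed waveform.

    Parameters
    ----------
    profile : ClassProfile
    config : SynthConfig
    seed : int
        Stream seed for this segment.
    speed_unstable : bool
        Inject a speed pattern the QC stage will reject.
    band_targets : array, optional
        Override the drawn band-fraction targets (must sum to 1).
    """
    duration = config.segment_duration_s
    rng = np.random.default_rng(seed)
    if band_targets is None:
        band_targets = gen_feature_samples(profile, 1, seed=int(rng.integers(2**31)))
        band_targets = band_targets[list(_feat.BAND_NAMES)].to_numpy()[0]
    else:
        band_targets = np.asarray(band_targets, dtype=float)
        if abs(band_targets.sum() - 1.0) > 1e-6:
            raise ValueError("band targets must sum to 1")

    t_local = _irregular_timestamps(duration, config.fs_mean_hz, config.fs_jitter, rng)
    mix = _design_modulus(band_targets, t_local, duration, config.lines_per_band,
                          config.preprocess, rng)
    m = mix(t_local)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    scale = rng.uniform(1.5, 3.5) / max(m.mean(), 1e-12)
    xyz = np.outer(m * scale, u)

    accel = pd.DataFrame(np.column_stack([t_start + t_local, xyz]),
                         columns=list(ACCEL_COLUMNS))
    track, _ = _gen_track(duration, t_start, profile, rng, speed_unstable,
                          alt0=alt0, dist0=dist0)
    return RawSegment(
        position=profile.position or "unknown",
        class_id=profile.class_id,
        accel=accel,
        track=track,
    )


@dataclass
class DatasetPaths:
    """Locations of the files written by :func:`gen_dataset`."""

    root: Path
    manifest: Path
    track: Path
    accel_dir: Path


def gen_dataset(
    config: SynthConfig,
    out_dir: str | Path,
    profiles: dict[tuple[str, str], ClassProfile] | None = None,
) -> DatasetPaths:
    """Write a complete synthetic dataset (accel CSVs, track CSV, manifest).

    Segments are laid out on a single global timeline with 2 s gaps.  Class
    labels cycle through c1..c4 within each position; the speed-unstable
    segments are chosen deterministically from the config seed.

    Raises
    ------
    KeyError
        If a requested (position, class) pair has no profile.
    """
    profiles = profiles or all_profiles()
    out = Path(out_dir)
    accel_dir = out / "accel"
    accel_dir.mkdir(parents=True, exist_ok=True)

    counts = config.position_counts()
    for pos in config.positions:
        for cid in CLASS_IDS:
            if (pos, cid) not in profiles:
                raise KeyError(f"missing profile for ({pos}, {cid})")

    manifest_rows = []
    track_parts = []
    t_cursor = 0.0
    alt, dist = 250.0, 0.0
    idx = 0
    for pos in config.positions:
        n_total, n_bad = counts[pos]
        pos_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xBAD, idx]))
        bad_set = set(pos_rng.choice(n_total, size=n_bad, replace=False).tolist())
        for j in range(n_total):
            cid = CLASS_IDS[j % len(CLASS_IDS)]
            seg_ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5EED, idx])
            seg_seed = int(seg_ss.generate_state(1)[0] % (2**31))
            seg = gen_raw_segment(
                profiles[(pos, cid)], config, seg_seed,
                speed_unstable=(j in bad_set),
                t_start=t_cursor, alt0=alt, dist0=dist,
            )
            seg_id = f"seg{idx:04d}"
            apath = f"accel/{seg_id}.csv"
            seg.accel.to_csv(out / apath, index=False, float_format="%.6f")
            track_parts.append(seg.track)
            manifest_rows.append({
                "segment_id": seg_id,
                "position": pos,
                "class_id": cid,
                "accel_path": apath,
                "t_start_s": round(t_cursor, 6),
                "t_end_s": round(t_cursor + config.segment_duration_s, 6),
                "speed_unstable": int(j in bad_set),
            })
            alt = float(seg.track["alt_m"].iloc[-1])
            dist = float(seg.track["dist_m"].iloc[-1])
            t_cursor += config.segment_duration_s + 2.0
            idx += 1

    track = pd.concat(track_parts, ignore_index=True)
    track_path = out / "track.csv"
    track.to_csv(track_path, index=False, float_format="%.6f")
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    config.to_yaml(out / "config.yaml")
    return DatasetPaths(root=out, manifest=manifest_path, track=track_path,
                        accel_dir=out)
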