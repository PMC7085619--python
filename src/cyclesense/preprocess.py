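"""Quality control, uniform resampling, FIR filtering and modulus reduction.

The processing chain for each segment is fixed:

1. per-axis linear interpolation of the irregular samples onto a uniform
   grid with the same endpoints and sample count;
2. causal FIR low-pass filtering of each axis (order ``M`` = 4 by default);
3. linear resampling onto the target rate (60 Hz by default);
4. per-sample Euclidean modulus of the three filtered axes.

Filtering precedes the modulus: the modulus is nonnegative, so low-passing
it would distort its mean level, whereas the recorded axis components are
ordinary signed signals.

The study quotes a 60 Hz low-pass cutoff together with resampling *to*
60 Hz, which cannot anti-alias (Nyquist is 30 Hz).  By default the
effective cutoff is therefore clamped to ``0.45 * fs_target``; set
``clamp_cutoff=False`` to run the literal printed parameters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .ingest import RawSegment

__all__ = [
    "PreprocessConfig",
    "UniformSegment",
    "QCResult",
    "qc_filter",
    "resample_uniform",
    "design_lowpass",
    "fir_filter",
    "modulus",
    "make_uniform_segment",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    Attributes
    ----------
    fs_target_hz : float
        Uniform rate of the final modulus series (60 Hz).
    fir_order : int
        Number of FIR taps ``M`` (the study uses 4).
    fir_cutoff_hz : float
        Nominal low-pass cutoff (the study quotes 60 Hz).
    qc_alpha : float
        A segment is rejected when std(speed) > alpha * mean(speed).
        The study calls alpha "a selected fraction" without a value.
    clamp_cutoff : bool
        Clamp the effective cutoff to ``0.45 * fs_target_hz`` so the filter
        actually anti-aliases before the final resampling.
    """

    fs_target_hz: float = 60.0
    fir_order: int = 4
    fir_cutoff_hz: float = 60.0
    qc_alpha: float = 0.5
    clamp_cutoff: bool = True

    def effective_cutoff(self, fs_stage_hz: float) -> float:
        """Cutoff actually used when filtering at ``fs_stage_hz``."""
        fc = self.fir_cutoff_hz
        if self.clamp_cutoff:
            fc = min(fc, 0.45 * self.fs_target_hz)
        return min(fc, 0.49 * fs_stage_hz)


@dataclass
class UniformSegment:
    """A preprocessed segment: uniform modulus series plus track summaries."""

    position: str
    class_id: str | None
    fs_hz: float
    modulus: np.ndarray
    hr_mean_bpm: float
    slope_pct: float
    speed_mean_ms: float
    speed_std_ms: float
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.modulus = np.asarray(self.modulus, dtype=float)
        if self.modulus.size < 2:
            raise ValueError("modulus series needs >= 2 samples")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if np.any(self.modulus < 0):
            raise ValueError("modulus values must be nonnegative")


@dataclass
class QCResult:
    kept: list[RawSegment]
    rejected: list[tuple[RawSegment, str]]

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.rejected)


def qc_filter(segments: list[RawSegment], alpha: float = 0.5) -> QCResult:
    """Reject segments whose speed is unstable.

    A segment is rejected iff ``std(speed) > alpha * mean(speed)`` (sample
    standard deviation, ddof=1) or its mean speed is nonpositive.

    Parameters
    ----------
    segments : list of RawSegment
    alpha : float
        Fraction of the mean speed used as the rejection threshold.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    kept: list[RawSegment] = []
    rejected: list[tuple[RawSegment, str]] = []
    for seg in segments:
        v = seg.track["speed_ms"].to_numpy(dtype=float)
        if v.size < 2:
            rejected.append((seg, "fewer than 2 speed samples"))
            continue
        mean = v.mean()
        if mean <= 0:
            rejected.append((seg, "nonpositive speed"))
            continue
        std = v.std(ddof=1)
        if std > alpha * mean:
            rejected.append((seg, f"speed std {std:.3f} > {alpha} * mean {mean:.3f}"))
        else:
            kept.append(seg)
    return QCResult(kept=kept, rejected=rejected)


def resample_uniform(t: np.ndarray, x: np.ndarray, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an irregular series onto a uniform grid.

    The output grid spans exactly ``[t[0], t[-1]]`` with ``n_out`` equally
    spaced points; the endpoint values are preserved bit for bit.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size != x.size:
        raise ValueError("t and x must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 input samples")
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if t[-1] == t[0]:
        raise ValueError("degenerate time span: t[0] == t[-1]")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    t_new = np.linspace(t[0], t[-1], n_out)
    x_new = np.interp(t_new, t, x)
    x_new[0], x_new[-1] = x[0], x[-1]
    return t_new, x_new


def design_lowpass(order: int, fc_hz: float, fs_hz: float) -> np.ndarray:
    """Hamming-windowed-sinc low-pass FIR with unity DC gain.

    Parameters
    ----------
    order : int
        Number of taps ``M`` (the causal convolution uses coefficients
        ``b(0)..b(M-1)``).
    fc_hz, fs_hz : float
        Cutoff and sampling frequency; requires ``0 < fc < fs/2``.

    Returns
    -------
    ndarray
        Symmetric (linear-phase) coefficients summing to 1.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < fc_hz < fs_hz / 2:
        raise ValueError(f"cutoff {fc_hz} Hz must lie in (0, fs/2 = {fs_hz / 2})")
    if order == 1:
        return np.array([1.0])
    return _sig.firwin(order, fc_hz, fs=fs_hz, window="hamming")


def fir_filter(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Causal FIR convolution ``x(n) = sum_k b(k) s(n-k)`` with zero initial state."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    x = np.asarray(x, dtype=float)
    if b.size == 0:
        raise ValueError("empty coefficient vector")
    if x.size < b.size:
        raise ValueError("series shorter than the filter")
    return _sig.lfilter(b, [1.0], x)


def modulus(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration components."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not ax.shape == ay.shape == az.shape:
        raise ValueError("component series must have equal length")
    if ax.size < 1:
        raise ValueError("empty input")
    return np.sqrt(ax * ax + ay * ay + az * az)


def make_uniform_segment(
    seg: RawSegment, config: PreprocessConfig | None = None
) -> UniformSegment:
    """Run the full per-segment chain and summarize the track.

    The heart rate is averaged over the segment window; the slope is
    ``100 * (alt_last - alt_first) / (dist_last - dist_first)``.
    """
    config = config or PreprocessConfig()
    seg.validate()
    t = seg.accel["t_s"].to_numpy(dtype=float)
    n1 = t.size
    span = t[-1] - t[0]
    fs1 = (n1 - 1) / span
    b = design_lowpass(config.fir_order, config.effective_cutoff(fs1), fs1)

    n2 = max(2, int(round(span * config.fs_target_hz)) + 1)
    fs2 = (n2 - 1) / span
    axes = []
    for col in ("ax_ms2", "ay_ms2", "az_ms2"):
        _, xu = resample_uniform(t, seg.accel[col].to_numpy(dtype=float), n1)
        xf = fir_filter(xu, b)
        tu = np.linspace(t[0], t[-1], n1)
        _, x2 = resample_uniform(tu, xf, n2)
        axes.append(x2)
    mod = modulus(*axes)

    track = seg.track
    hr = track["hr_bpm"].to_numpy(dtype=float)
    alt = track["alt_m"].to_numpy(dtype=float)
    dist = track["dist_m"].to_numpy(dtype=float)
    v = track["speed_ms"].to_numpy(dtype=float)
    d_dist = dist[-1] - dist[0]
    if d_dist <= 0:
        raise ValueError(f"segment {seg.segment_id}: nonpositive distance span")
    return UniformSegment(
        position=seg.position,
        class_id=seg.class_id,
        fs_hz=fs2,
        modulus=mod,
        hr_mean_bpm=float(hr.mean()),
        slope_pct=float(100.0 * (alt[-1] - alt[0]) / d_dist),
        speed_mean_ms=float(v.mean()),
        speed_std_ms=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        segment_id=seg.segment_id,
    )
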