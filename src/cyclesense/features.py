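"""Relative band powers and the feature matrix P(R, Q).

Each segment contributes a column of R = 5 features: the relative DFT power
of the acceleration modulus in four contiguous bands forming a complete
filter bank over <0, fs/2> Hz, plus the mean heart rate.

The relative power in a band <fc1, fc2> is

    PV = sum_{k in Phi} |Y(k)|^2 / sum_{k=0}^{N/2} |Y(k)|^2,

with ``Y`` the DFT of the segment and ``Phi`` the bins whose frequencies
fall in the band.  Band membership is half-open ``[fc1, fc2)`` with the
final band closed at Nyquist, so the four band powers of any segment sum
to exactly 1.

The published per-class feature tables (band-1 fractions of 39-71%) are
only attainable for spectra of *de-meaned* moduli: the modulus is a
nonnegative signal, every DFT magnitude of a nonnegative sequence is
bounded by its DC bin, and with DC retained band 1 would dominate at the
85%+ level for any realistic recording.  :func:`segment_features` therefore
subtracts the segment mean before the DFT (``detrend=True``), while
:func:`band_power` evaluates the quoted formula verbatim on whatever series
it is given.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import UniformSegment

__all__ = [
    "BAND_NAMES",
    "FEATURE_NAMES",
    "BandSpec",
    "FeatureMatrix",
    "ZeroSignalError",
    "FlatSlopeError",
    "band_power",
    "segment_features",
    "build_feature_matrix",
    "slope_to_class",
    "binary_labels",
]

BAND_NAMES = ("F0_3", "F3_8", "F8_15", "F15_30")
FEATURE_NAMES = BAND_NAMES + ("HR",)


class ZeroSignalError(ValueError):
    """Band power is undefined for an all-zero signal."""


class FlatSlopeError(ValueError):
    """A slope of exactly zero maps to no terrain class."""


@dataclass(frozen=True)
class BandSpec:
    """Ordered band edges (Hz) defining contiguous analysis bands."""

    edges: tuple[float, ...] = (0.0, 3.0, 8.0, 15.0, 30.0)

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("band edges must be strictly increasing")

    @property
    def bands(self) -> list[tuple[float, float]]:
        return list(zip(self.edges, self.edges[1:]))

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1


def band_power(
    y: np.ndarray,
    fs_hz: float,
    band: tuple[float, float],
    *,
    nyquist_closed: bool | None = None,
) -> float:
    """Relative DFT power of ``y`` in the frequency band ``[fc1, fc2)``.

    Parameters
    ----------
    y : ndarray
        Uniformly sampled series, N >= 4.
    fs_hz : float
        Sampling rate.
    band : (float, float)
        Band edges; requires ``0 <= fc1 < fc2 <= fs/2`` (a small tolerance
        above Nyquist is accepted for rates that round to the target).
    nyquist_closed : bool, optional
        Include the Nyquist bin.  Defaults to automatic: closed when ``fc2``
        reaches ``fs/2``.

    Returns
    -------
    float
        Power fraction in [0, 1]; the denominator spans bins 0..N/2.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need N >= 4 samples")
    fc1, fc2 = band
    nyq = fs_hz / 2.0
    if not 0 <= fc1 < fc2:
        raise ValueError(f"invalid band {band}")
    if fc2 > nyq * 1.02 + 1e-9:
        raise ValueError(f"band top {fc2} Hz exceeds Nyquist {nyq} Hz")
    power = np.abs(np.fft.rfft(y)) ** 2
    denom = power.sum()
    if denom == 0.0:
        raise ZeroSignalError("band power undefined for an all-zero signal")
    if nyquist_closed is None:
        nyquist_closed = fc2 >= nyq * (1.0 - 1e-12)
    # bin k belongs to the band iff fc1 <= k fs / N < fc2; comparing the
    # products k*fs vs fc*N keeps edge bins (k fs/N exactly on an edge)
    # assigned consistently.  rfft bins stop at N/2, so a Nyquist-closed
    # band needs no upper bound.
    kfs = np.arange(power.size) * float(fs_hz)
    mask = (kfs >= fc1 * n) if nyquist_closed else (kfs >= fc1 * n) & (kfs < fc2 * n)
    return float(power[mask].sum() / denom)


def segment_features(
    seg: UniformSegment,
    bands: BandSpec | None = None,
    *,
    detrend: bool = True,
) -> np.ndarray:
    """Feature vector (PV per band, then mean heart rate) of one segment.

    The segment mean is removed before the DFT by default (see module
    docstring); the band masks still cover the full 0..fs/2 range, so the
    band powers sum to 1 regardless.
    """
    bands = bands or BandSpec()
    nyq = seg.fs_hz / 2.0
    top = bands.edges[-1]
    if top > nyq * 1.02 or top < nyq * 0.98:
        raise ValueError(
            f"final band edge {top} Hz must match the segment Nyquist {nyq:.3f} Hz"
        )
    y = seg.modulus - seg.modulus.mean() if detrend else seg.modulus
    pv = [
        band_power(y, seg.fs_hz, bnd, nyquist_closed=(i == bands.n_bands - 1))
        for i, bnd in enumerate(bands.bands)
    ]
    return np.array(pv + [seg.hr_mean_bpm])


@dataclass
class FeatureMatrix:
    """The feature matrix P(R, Q) with targets and positions per column."""

    P: np.ndarray
    targets: np.ndarray
    positions: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.targets = np.asarray(self.targets)
        self.positions = np.asarray(self.positions)
        if self.P.ndim != 2 or self.P.shape[0] != len(self.feature_names):
            raise ValueError(
                f"P must be {len(self.feature_names)} x Q, got {self.P.shape}"
            )
        if self.P.shape[1] == 0:
            raise ValueError("feature matrix has no columns")
        if not (self.P.shape[1] == self.targets.size == self.positions.size):
            raise ValueError("P, targets and positions must agree in Q")

    @property
    def Q(self) -> int:
        return self.P.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Samples-by-features view (Q x R), the layout classifiers consume."""
        return self.P.T

    def select(
        self,
        *,
        positions: list[str] | None = None,
        features: list[str] | None = None,
    ) -> "FeatureMatrix":
        """Subset columns by position and/or rows by feature name."""
        col = np.ones(self.Q, dtype=bool)
        if positions is not None:
            col &= np.isin(self.positions, positions)
            if not col.any():
                raise ValueError(f"no segments at positions {positions}")
        names = self.feature_names
        rows = np.arange(len(names))
        if features is not None:
            unknown = set(features) - set(names)
            if unknown:
                raise KeyError(f"unknown features {sorted(unknown)}")
            rows = np.array([names.index(f) for f in features])
            names = tuple(features)
        return FeatureMatrix(
            P=self.P[np.ix_(rows, np.where(col)[0])],
            targets=self.targets[col],
            positions=self.positions[col],
            feature_names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P.T, columns=list(self.feature_names))
        df.insert(0, "class", self.targets)
        df.insert(0, "position", self.positions)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   feature_names: tuple[str, ...] = FEATURE_NAMES) -> "FeatureMatrix":
        return cls(
            P=df[list(feature_names)].to_numpy().T,
            targets=df["class"].to_numpy(),
            positions=df["position"].to_numpy(),
            feature_names=feature_names,
        )


def build_feature_matrix(
    segments: list[UniformSegment], bands: BandSpec | None = None, **kw
) -> FeatureMatrix:
    """Stack per-segment feature vectors into P(5, Q) with aligned labels."""
    if not segments:
        raise ValueError("no segments")
    bands = bands or BandSpec()
    cols = [segment_features(s, bands, **kw) for s in segments]
    return FeatureMatrix(
        P=np.column_stack(cols),
        targets=np.array([s.class_id for s in segments]),
        positions=np.array([s.position for s in segments]),
    )


def slope_to_class(slope_pct: float, steep_threshold_pct: float = 15.0) -> str:
    """Map a mean terrain grade to a class id.

    ``|slope| >= steep_threshold_pct`` gives the steep classes (c3 uphill,
    c4 downhill); milder grades give c1/c2.  Zero slope is an error: the
    study has no flat class.
    """
    if not np.isfinite(slope_pct):
        raise ValueError(f"invalid slope {slope_pct}")
    if slope_pct == 0.0:
        raise FlatSlopeError("slope is exactly 0; no flat terrain class exists")
    steep = abs(slope_pct) >= steep_threshold_pct
    if slope_pct > 0:
        return "c3" if steep else "c1"
    return "c4" if steep else "c2"


def binary_labels(targets: np.ndarray) -> np.ndarray:
    """Collapse the four terrain classes to the uphill/downhill binary task.

    Class A (uphill) is c1 + c3; class B (downhill) is c2 + c4.
    """
    targets = np.asarray(targets)
    unknown = set(np.unique(targets)) - {"c1", "c2", "c3", "c4"}
    if unknown:
        raise ValueError(f"unknown class ids {sorted(unknown)}")
    return np.where(np.isin(targets, ("c1", "c3")), "A", "B")
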