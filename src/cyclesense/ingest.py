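"""Readers for accelerometer / track CSV exports and segment assembly.

The pipeline consumes two plain-text formats:

* accelerometer CSV with columns ``t_s, ax_ms2, ay_ms2, az_ms2``
  (seconds; m/s^2 of linear acceleration, gravity already removed), sampled
  irregularly (phone exports run at ~142 Hz on average);
* track CSV with columns ``t_s, lat_deg, lon_deg, alt_m, dist_m, speed_ms,
  hr_bpm`` -- the CSV conversion of a Garmin TCX export (~0.48 Hz).

A manifest CSV maps each labeled segment to its accelerometer file and time
window.  Cleaning performed here is deliberately minimal and documented:
rows with missing values are dropped, duplicate timestamps are collapsed by
mean, and out-of-order rows are sorted (with a warning).
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ACCEL_COLUMNS",
    "TRACK_COLUMNS",
    "FormatError",
    "EmptyInputError",
    "RawSegment",
    "IngestProblem",
    "AssembledDataset",
    "read_accel_csv",
    "read_track_csv",
    "assemble_segments",
]

ACCEL_COLUMNS = ("t_s", "ax_ms2", "ay_ms2", "az_ms2")
TRACK_COLUMNS = ("t_s", "lat_deg", "lon_deg", "alt_m", "dist_m", "speed_ms", "hr_bpm")


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


class EmptyInputError(ValueError):
    """A series has fewer than two usable samples."""


@dataclass
class RawSegment:
    """One labeled cycling segment before preprocessing.

    Attributes
    ----------
    position : str
        Sensor position name (e.g. ``Spine2``).
    class_id : str or None
        Terrain class ``c1``..``c4``; ``None`` for unlabeled data.
    accel : pandas.DataFrame
        Irregular tri-axial series with columns :data:`ACCEL_COLUMNS`.
    track : pandas.DataFrame
        Track series with columns :data:`TRACK_COLUMNS`.
    segment_id : str
        Identifier from the manifest.
    """

    position: str
    class_id: str | None
    accel: pd.DataFrame
    track: pd.DataFrame
    segment_id: str = ""

    def validate(self) -> None:
        """Check the structural invariants of a usable segment."""
        for df, cols, name in ((self.accel, ACCEL_COLUMNS, "accel"),
                               (self.track, TRACK_COLUMNS, "track")):
            missing = set(cols) - set(df.columns)
            if missing:
                raise FormatError(f"{name} series missing columns {sorted(missing)}")
            if len(df) < 2:
                raise EmptyInputError(f"{name} series has {len(df)} samples; need >= 2")
            t = df["t_s"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} timestamps must be strictly increasing")
        a, b = self.accel["t_s"], self.track["t_s"]
        if a.iloc[-1] < b.iloc[0] or b.iloc[-1] < a.iloc[0]:
            raise ValueError("accel and track time ranges do not overlap")


@dataclass
class IngestProblem:
    """A manifest row that could not be turned into a usable segment."""

    segment_id: str
    reason: str


@dataclass
class AssembledDataset:
    """Result of :func:`assemble_segments`."""

    segments: list[RawSegment]
    problems: list[IngestProblem] = field(default_factory=list)

    @property
    def counts_by_position(self) -> dict[str, int]:
        return dict(Counter(s.position for s in self.segments))


def _read_series(path: str | Path, columns: tuple[str, ...], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"{kind} file {path} missing columns {sorted(missing)}")
    df = df[list(columns)]
    n_raw = len(df)
    df = df.dropna()
    if n_raw - len(df):
        warnings.warn(f"{path}: dropped {n_raw - len(df)} rows with missing values",
                      stacklevel=3)
    t = df["t_s"].to_numpy()
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: timestamps out of order; sorting", stacklevel=3)
        df = df.sort_values("t_s", kind="stable")
    if df["t_s"].duplicated().any():
        df = df.groupby("t_s", as_index=False).mean()
    if len(df) < 2:
        raise EmptyInputError(f"{kind} file {path} has {len(df)} usable rows; need >= 2")
    return df.reset_index(drop=True)


def read_accel_csv(path: str | Path) -> pd.DataFrame:
    """Read and clean an accelerometer CSV.

    Returns a DataFrame with exactly the four accelerometer columns, strictly
    increasing timestamps, no missing values.
    """
    return _read_series(path, ACCEL_COLUMNS, "accelerometer")


def read_track_csv(path: str | Path) -> pd.DataFrame:
    """Read and clean a track CSV (time, position, altitude, distance, speed, HR)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(head.columns)
    if missing:
        raise FormatError(f"track file {path} missing columns {sorted(missing)}")
    if head["hr_bpm"].isna().all():
        raise FormatError(f"track file {path}: column 'hr_bpm' is empty")
    return _read_series(path, TRACK_COLUMNS, "track")


def _crop(df: pd.DataFrame, t_start: float, t_end: float) -> pd.DataFrame:
    # half-open window [t_start, t_end) so boundary samples belong to one segment
    m = (df["t_s"] >= t_start) & (df["t_s"] < t_end)
    return df.loc[m].reset_index(drop=True)


def assemble_segments(
    manifest: pd.DataFrame | str | Path,
    accel_dir: str | Path,
    track: pd.DataFrame | str | Path,
) -> AssembledDataset:
    """Assemble labeled :class:`RawSegment` objects from a manifest.

    Parameters
    ----------
    manifest : DataFrame or path
        One row per segment with columns ``segment_id, position, class_id,
        accel_path, t_start_s, t_end_s``.
    accel_dir : path
        Directory against which relative ``accel_path`` entries resolve.
    track : DataFrame or path
        The single track series covering all segments.

    Returns
    -------
    AssembledDataset
        Usable segments plus explicitly flagged problems (a window with no
        accelerometer overlap is reported, never silently dropped).

    Raises
    ------
    FileNotFoundError
        If a manifest row references a missing accelerometer file; the error
        names the offending row.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"segment_id", "position", "class_id", "accel_path", "t_start_s", "t_end_s"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns {sorted(missing)}")
    if not isinstance(track, pd.DataFrame):
        track = read_track_csv(track)
    accel_dir = Path(accel_dir)

    segments: list[RawSegment] = []
    problems: list[IngestProblem] = []
    for idx, row in manifest.iterrows():
        seg_id = str(row["segment_id"])
        apath = accel_dir / str(row["accel_path"])
        if not apath.exists():
            raise FileNotFoundError(
                f"manifest row {idx} (segment {seg_id}): accel file {apath} not found"
            )
        accel = read_accel_csv(apath)
        t0, t1 = float(row["t_start_s"]), float(row["t_end_s"])
        if not t1 > t0:
            problems.append(IngestProblem(seg_id, f"invalid window [{t0}, {t1})"))
            continue
        seg = RawSegment(
            position=str(row["position"]),
            class_id=None if pd.isna(row["class_id"]) else str(row["class_id"]),
            accel=_crop(accel, t0, t1),
            track=_crop(track, t0, t1),
            segment_id=seg_id,
        )
        try:
            seg.validate()
        except (EmptyInputError, ValueError) as exc:
            problems.append(IngestProblem(seg_id, str(exc)))
            continue
        segments.append(seg)
    return AssembledDataset(segments=segments, problems=problems)
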