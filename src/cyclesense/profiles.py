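"""Published per-class statistics of the cycling study that this package models.

The study recorded 1293 cycling segments with a phone accelerometer at seven
body positions and a Garmin watch (GPS + chest-strap heart rate).  Segments
are labeled by terrain class from the GPS slope:

================  =====================  ==================
class id          name                   mean slope [%]
================  =====================  ==================
``c1``            HillUp                 10.3 +- 3.3
``c2``            HillDown               -9.4 +- 3.9
``c3``            SteepHillUp            19.8 +- 3.4
``c4``            SteepHillDown          -18.7 +- 3.4
================  =====================  ==================

For every (position, class) cell the study reports the mean and standard
deviation of five features: the relative spectral power of the acceleration
modulus in the bands <0,3>, <3,8>, <8,15> and <15,30> Hz (percent) and the
mean heart rate (bpm).  Those printed statistics are the parameters of the
synthetic-data generator in :mod:`cyclesense.synth`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "POSITIONS",
    "CLASS_IDS",
    "CLASS_NAMES",
    "SEGMENT_COUNTS",
    "SLOPE_STATS",
    "ClassProfile",
    "table_profile",
    "all_profiles",
]

#: Sensor positions, in the study's table order.
POSITIONS = ("LeftLeg", "RightLeg", "Spine1", "Spine2", "LeftArm", "RightArm", "Neck")

#: Terrain classes.
CLASS_IDS = ("c1", "c2", "c3", "c4")

CLASS_NAMES = {
    "c1": "HillUp",
    "c2": "HillDown",
    "c3": "SteepHillUp",
    "c4": "SteepHillDown",
}

#: Per-position (total segments recorded, segments rejected by the speed QC).
#: Totals: 1293 recorded, 39 rejected, 1254 kept.
SEGMENT_COUNTS = {
    "LeftLeg": (180, 6),
    "RightLeg": (210, 9),
    "Spine1": (177, 9),
    "Spine2": (174, 6),
    "LeftArm": (177, 3),
    "RightArm": (198, 0),
    "Neck": (177, 6),
}

#: Per-class (mean slope %, std) as recorded by the GPS.
SLOPE_STATS = {
    "c1": (10.3, 3.3),
    "c2": (-9.4, 3.9),
    "c3": (19.8, 3.4),
    "c4": (-18.7, 3.4),
}

# Per (position, class): band-power means [%], band-power stds [%],
# heart-rate mean [bpm], heart-rate std [bpm].
_FEATURE_TABLE = {
    "LeftLeg": {
        "c1": ((66, 25, 7, 2), (7, 5, 2, 1), 137, 22),
        "c2": ((52, 33, 12, 3), (7, 6, 2, 1), 129, 19),
        "c3": ((59, 29, 8, 3), (6, 5, 2, 1), 142, 26),
        "c4": ((56, 32, 10, 3), (7, 4, 2, 2), 122, 17),
    },
    "RightLeg": {
        "c1": ((71, 21, 6, 2), (5, 4, 1, 1), 142, 20),
        "c2": ((51, 34, 12, 3), (7, 4, 3, 2), 125, 23),
        "c3": ((64, 25, 8, 3), (6, 4, 2, 1), 139, 26),
        "c4": ((58, 29, 10, 3), (6, 4, 2, 1), 123, 24),
    },
    "Spine1": {
        "c1": ((44, 41, 12, 3), (7, 6, 3, 2), 146, 16),
        "c2": ((50, 36, 12, 3), (8, 5, 3, 2), 130, 18),
        "c3": ((44, 42, 10, 4), (10, 8, 2, 1), 126, 25),
        "c4": ((58, 29, 11, 3), (7, 5, 2, 2), 114, 18),
    },
    "Spine2": {
        "c1": ((39, 41, 16, 4), (5, 4, 2, 1), 137, 11),
        "c2": ((53, 33, 11, 4), (7, 5, 2, 1), 127, 11),
        "c3": ((39, 47, 11, 3), (7, 7, 3, 1), 133, 17),
        "c4": ((64, 25, 9, 3), (7, 5, 1, 0), 119, 13),
    },
    "LeftArm": {
        "c1": ((48, 36, 13, 3), (6, 4, 3, 2), 144, 13),
        "c2": ((50, 34, 12, 4), (6, 4, 2, 2), 140, 12),
        "c3": ((47, 38, 12, 3), (5, 3, 2, 2), 136, 18),
        "c4": ((60, 27, 10, 3), (6, 4, 3, 1), 120, 16),
    },
    "RightArm": {
        "c1": ((47, 38, 12, 3), (6, 4, 2, 1), 153, 11),
        "c2": ((50, 36, 11, 3), (7, 5, 2, 2), 138, 11),
        "c3": ((52, 34, 11, 3), (5, 3, 2, 2), 151, 20),
        "c4": ((61, 28, 9, 3), (5, 3, 2, 1), 128, 14),
    },
    "Neck": {
        "c1": ((49, 36, 12, 4), (7, 4, 3, 1), 145, 13),
        "c2": ((53, 34, 11, 3), (8, 5, 4, 2), 142, 12),
        "c3": ((52, 35, 10, 3), (7, 6, 2, 1), 134, 18),
        "c4": ((57, 31, 10, 3), (5, 4, 2, 1), 128, 14),
    },
}


@dataclass(frozen=True)
class ClassProfile:
    """Statistical profile of one (position, terrain class) cell.

    Band fractions are dimensionless in [0, 1] (the study prints them as
    rounded percentages, so the means sum to 1 within 0.02).

    Parameters
    ----------
    class_id : str
        One of ``c1``..``c4``.
    band_means, band_stds : tuple of 4 floats
        Mean and standard deviation of the relative power in the bands
        <0,3>, <3,8>, <8,15>, <15,30> Hz.
    hr_mean_bpm, hr_std_bpm : float
        Heart-rate statistics in beats/min.
    slope_mean_pct, slope_std_pct : float
        Terrain grade statistics in percent.
    """

    class_id: str
    band_means: tuple[float, float, float, float]
    band_stds: tuple[float, float, float, float]
    hr_mean_bpm: float
    hr_std_bpm: float
    slope_mean_pct: float = 0.0
    slope_std_pct: float = 0.0
    position: str = ""

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"unknown class id {self.class_id!r}")
        if len(self.band_means) != 4 or len(self.band_stds) != 4:
            raise ValueError("band_means and band_stds must have 4 entries")
        total = float(sum(self.band_means))
        if abs(total - 1.0) > 0.02:
            raise ValueError(
                f"band-fraction means sum to {total:.4f}; must be 1 within 0.02"
            )
        if any(s < 0 for s in self.band_stds) or self.hr_std_bpm < 0 or self.slope_std_pct < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 40.0 <= self.hr_mean_bpm <= 220.0:
            raise ValueError(f"hr_mean_bpm {self.hr_mean_bpm} outside [40, 220]")


def table_profile(position: str, class_id: str) -> ClassProfile:
    """Build the :class:`ClassProfile` for one study cell.

    Band percentages are converted to fractions; slope statistics are the
    per-class values shared by all positions.
    """
    try:
        means, stds, hr_mean, hr_std = _FEATURE_TABLE[position][class_id]
    except KeyError as exc:
        raise KeyError(f"no profile for position={position!r}, class={class_id!r}") from exc
    slope_mean, slope_std = SLOPE_STATS[class_id]
    return ClassProfile(
        class_id=class_id,
        band_means=tuple(m / 100.0 for m in means),
        band_stds=tuple(s / 100.0 for s in stds),
        hr_mean_bpm=float(hr_mean),
        hr_std_bpm=float(hr_std),
        slope_mean_pct=slope_mean,
        slope_std_pct=slope_std,
        position=position,
    )


def all_profiles() -> dict[tuple[str, str], ClassProfile]:
    """All 28 (position, class) profiles of the study."""
    return {
        (pos, cid): table_profile(pos, cid)
        for pos in POSITIONS
        for cid in CLASS_IDS
    }
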