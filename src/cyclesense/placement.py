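"""Cluster-separability criterion for ranking sensor positions.

For a pair of terrain classes (k, l), a sensor position and a pair of
features, the criterion compares the Euclidean distance D between the two
class centroids with the sum ST of the cluster spreads:

    Z = (D - ST) / D

Z is positive exactly when the centroid distance exceeds the summed
spreads (compact, well-separated clusters), and approaches 1 for
point-like clusters far apart.  The normalization by D makes Z
dimensionless and invariant under rigid motions and common rescaling of
the feature plane; the raw difference ``D - ST`` is available with
``normalization="none"``.

The spread of a 2-D cluster is the root-mean-square Euclidean distance of
its points to the centroid, which is rotation invariant and reduces to the
ordinary standard deviation in one dimension.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

__all__ = ["ClusterStats", "CriterionResult", "cluster_stats", "criterion",
           "rank_positions"]


@dataclass(frozen=True)
class ClusterStats:
    """Centroid, spread and size of one feature-plane cluster."""

    center: tuple[float, float]
    spread: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a cluster needs at least 2 members")
        if self.spread < 0:
            raise ValueError("spread must be nonnegative")


@dataclass(frozen=True)
class CriterionResult:
    """Separability of one class pair at one position."""

    Z: float
    D: float
    ST: float
    position: str = ""
    class_pair: tuple[str, str] = ("", "")
    feature_pair: tuple[str, str] = ("", "")


def cluster_stats(points: np.ndarray) -> ClusterStats:
    """Centroid and RMS-distance spread of an n x 2 point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an n x 2 array, got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    center = pts.mean(axis=0)
    spread = float(np.sqrt(np.mean(np.sum((pts - center) ** 2, axis=1))))
    return ClusterStats(center=(float(center[0]), float(center[1])),
                        spread=spread, n=pts.shape[0])


def criterion(
    stats_k: ClusterStats,
    stats_l: ClusterStats,
    *,
    normalization: str = "distance",
    position: str = "",
    class_pair: tuple[str, str] = ("", ""),
    feature_pair: tuple[str, str] = ("", ""),
) -> CriterionResult:
    """Evaluate the separability criterion for two clusters.

    ``normalization="distance"`` gives Z = (D - ST)/D (dimensionless, <= 1);
    ``"none"`` gives the raw difference D - ST.  Coincident centers yield
    Z = -inf, the worst possible separability.
    """
    if normalization not in ("distance", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ck = np.asarray(stats_k.center)
    cl = np.asarray(stats_l.center)
    D = float(np.linalg.norm(ck - cl))
    ST = stats_k.spread + stats_l.spread
    if D == 0.0:
        Z = float("-inf")
    elif normalization == "distance":
        Z = (D - ST) / D
    else:
        Z = D - ST
    return CriterionResult(Z=Z, D=D, ST=ST, position=position,
                           class_pair=class_pair, feature_pair=feature_pair)


def rank_positions(
    fm: FeatureMatrix,
    class_pair: tuple[str, str] = ("c3", "c4"),
    feature_pair: tuple[str, str] = ("F0_3", "HR"),
    *,
    normalization: str = "distance",
    standardize: bool = False,
) -> list[CriterionResult]:
    """Rank every position by the separability of one class pair.

    Parameters
    ----------
    fm : FeatureMatrix
        Features for all positions.
    class_pair, feature_pair : tuples
        Classes and the two features defining the cluster plane.
    standardize : bool
        Z-score each feature over all segments first.  Off by default (the
        study plots raw percent and bpm axes), but useful because the two
        features otherwise carry different units.

    Returns
    -------
    list of CriterionResult
        Sorted by Z descending; ties broken by position name.

    Raises
    ------
    ValueError
        If some position lacks two members of either class.
    """
    sub = fm.select(features=list(feature_pair))
    X = sub.X.copy()
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    results = []
    for pos in sorted(set(sub.positions.tolist())):
        at_pos = sub.positions == pos
        stats = []
        for cid in class_pair:
            pts = X[at_pos & (sub.targets == cid)]
            if pts.shape[0] < 2:
                raise ValueError(
                    f"position {pos} has {pts.shape[0]} segments of class {cid}; "
                    "need >= 2"
                )
            stats.append(cluster_stats(pts))
        results.append(criterion(stats[0], stats[1], normalization=normalization,
                                 position=pos, class_pair=class_pair,
                                 feature_pair=feature_pair))
    results.sort(key=lambda r: (-r.Z, r.position))
    return results
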