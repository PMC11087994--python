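"""Clustering of the 168 hour-of-week slots into ordered congestion levels.

Hours with similar city-mean travel times are grouped with k-means into K
clusters and relabelled so level 1 is free-flow (lowest mean) and level K is
peak.  A per-TAZ audit reports zones whose own level ordering deviates from
the city-wide ordering (adjacent-level inversions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synthetic_city import HOURS_PER_WEEK, HourlyTravelTensor


@dataclass
class CongestionClustering:
    """Assignment of each hour of the week to an ordered congestion level.

    ``level_of_hour[h]`` is in 1..K with level means strictly increasing,
    so 1 = free-flow and K = peak traffic.
    """

    level_of_hour: np.ndarray  # (168,) int, values 1..K
    K: int
    level_mean_minutes: np.ndarray  # (K,) city-mean minutes per level

    def hours_of_level(self, level: int) -> np.ndarray:
        self._check_level(level)
        return np.nonzero(self.level_of_hour == level)[0]

    def _check_level(self, level: int) -> None:
        if not 1 <= level <= self.K:
            raise ValueError(f"level {level} outside 1..{self.K}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hour_of_week": np.arange(HOURS_PER_WEEK), "level": self.level_of_hour}
        )


@dataclass
class OrderingAudit:
    """Per-TAZ count of adjacent congestion-level inversions.

    An inversion is an adjacent pair of city-wide levels whose order of mean
    outgoing travel time is reversed for that TAZ; at most K-1 adjacent
    transpositions are counted per zone.
    """

    inversions_by_taz: pd.Series  # index taz_id, value inversion count
    n_taz_with_inversion: int
    total_inversions: int


def cluster_hours(
    tensor: HourlyTravelTensor, K: int = 9, seed: int = 0
) -> CongestionClustering:
    """Partition the week's hours into K ordered congestion levels.

    k-means (10 restarts, fixed seed) on the standardized city-mean
    travel-time-per-hour vector; cluster labels are then re-ordered by
    ascending cluster mean, ties broken by the lower original label.  A
    constant profile collapses to a single level with a warning.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > HOURS_PER_WEEK:
        raise ValueError(f"K={K} exceeds the {HOURS_PER_WEEK} weekly hours")
    profile = tensor.city_mean_profile()
    if np.ptp(profile) == 0 or K == 1:
        if K > 1:
            warnings.warn(
                "constant congestion profile: all hours assigned level 1, "
                f"K collapses from {K} to 1",
                stacklevel=2,
            )
        return CongestionClustering(
            level_of_hour=np.ones(HOURS_PER_WEEK, dtype=np.int64),
            K=1,
            level_mean_minutes=np.array([profile.mean()]),
        )
    z = (profile - profile.mean()) / profile.std()
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    raw = km.fit_predict(z.reshape(-1, 1))
    raw_means = np.array([profile[raw == c].mean() for c in range(K)])
    order = np.lexsort((np.arange(K), raw_means))  # ascending mean, tie -> lower label
    rank_of_raw = np.empty(K, dtype=np.int64)
    rank_of_raw[order] = np.arange(1, K + 1)
    levels = rank_of_raw[raw]
    level_means = raw_means[order]
    return CongestionClustering(
        level_of_hour=levels, K=K, level_mean_minutes=level_means
    )


def hours_share(clustering: CongestionClustering, level: int) -> float:
    """Fraction of the week's 168 hours assigned to ``level``."""
    clustering._check_level(level)
    return int((clustering.level_of_hour == level).sum()) / HOURS_PER_WEEK


def audit_taz_ordering(
    tensor: HourlyTravelTensor, clustering: CongestionClustering
) -> OrderingAudit:
    """Check, per origin TAZ, that level means follow the city-wide order.

    For each origin, outgoing travel times are averaged per level (over
    destinations and the level's hours); each adjacent pair of levels whose
    means are strictly decreasing counts as one inversion.
    """
    dest_is_origin = np.equal.outer(
        np.asarray(tensor.origin_ids, dtype=object),
        np.asarray(tensor.dest_ids, dtype=object),
    )
    level_means = np.empty((len(tensor.origin_ids), clustering.K))
    for lvl in range(1, clustering.K + 1):
        hrs = clustering.hours_of_level(lvl)
        level_means[:, lvl - 1] = np.where(
            dest_is_origin, np.nan, tensor.minutes[:, :, hrs].mean(axis=2)
        ).mean(axis=1, where=~dest_is_origin)
    inv = (np.diff(level_means, axis=1) < 0).sum(axis=1)
    counts = pd.Series(inv, index=pd.Index(tensor.origin_ids, name="taz_id"))
    return OrderingAudit(
        inversions_by_taz=counts,
        n_taz_with_inversion=int((counts > 0).sum()),
        total_inversions=int(counts.sum()),
    )
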