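"""Sampled origin-destination travel times and their predictive reconstruction.

The full weekly grid (every origin, every destination, 168 hours) is
prohibitively expensive to measure; the pipeline instead samples travel times
only to service-hosting destinations and per congestion level, then
reconstructs the complete per-level origin-destination matrix with a
per-level linear regression on free-flow time.  Each TAZ's shortest time to a
service is derived from the reconstructed tensor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import isotonic_rows, round_half_up_int
from .congestion import CongestionClustering
from .synthetic_city import (
    HOURS_PER_WEEK,
    HourlyTravelTensor,
    ServiceFacility,
    TrafficAnalysisZone,
)


@dataclass(frozen=True)
class SamplingPlan:
    """Which origin-destination-level cells are measured directly."""

    origin_ids: tuple[str, ...]
    dest_ids: tuple[str, ...]
    K: int

    @property
    def sample_size(self) -> int:
        return len(self.origin_ids) * len(self.dest_ids) * self.K


@dataclass
class TravelTimeTensor:
    """Per-level origin-destination minutes, sampled cells plus predictions.

    ``sampled_mask[o, d, k]`` flags cells measured directly; the rest are
    regression estimates.  ``alpha``/``beta`` are the per-level intercepts
    and slopes of the reconstruction fit.
    """

    origin_ids: list[str]
    minutes: np.ndarray  # (n, n, K), destinations in origin order
    free_flow: np.ndarray  # (n, n)
    K: int
    alpha: np.ndarray  # (K,)
    beta: np.ndarray  # (K,)
    sampled_mask: np.ndarray  # (n, n, K) bool

    def index_of(self, taz_id: str) -> int:
        return self.origin_ids.index(taz_id)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.origin_ids)
        o, d, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(self.K), indexing="ij")
        keep = (o != d).ravel()
        ids = np.asarray(self.origin_ids, dtype=object)
        return pd.DataFrame(
            {
                "origin_taz": ids[o.ravel()[keep]],
                "dest_taz": ids[d.ravel()[keep]],
                "level": k.ravel()[keep] + 1,
                "minutes": self.minutes.ravel()[keep],
                "provenance": np.where(
                    self.sampled_mask.ravel()[keep], "sampled", "estimated"
                ),
            }
        )


@dataclass
class NearestServiceTimes:
    """Shortest travel time from each origin to any service, per level."""

    origin_ids: list[str]
    shortest_minutes: np.ndarray  # (n, K)
    nearest_service_taz: np.ndarray  # (n, K) object array of TAZ ids
    K: int

    def to_frame(self) -> pd.DataFrame:
        n = len(self.origin_ids)
        o, k = np.meshgrid(np.arange(n), np.arange(self.K), indexing="ij")
        ids = np.asarray(self.origin_ids, dtype=object)
        return pd.DataFrame(
            {
                "origin_taz": ids[o.ravel()],
                "level": k.ravel() + 1,
                "shortest_minutes": self.shortest_minutes.ravel(),
                "nearest_service_taz": self.nearest_service_taz.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# sampling plan arithmetic
# ---------------------------------------------------------------------------


def build_sampling_plan(
    zones: Sequence[TrafficAnalysisZone],
    services: Sequence[ServiceFacility],
    K: int = 9,
    extra_dest_tazs: Sequence[str] = (),
) -> SamplingPlan:
    """Sample every origin against service-hosting TAZs (plus extras) per level."""
    if not services:
        raise ValueError("at least one service is required to build a plan")
    origin_ids = tuple(z.taz_id for z in zones)
    universe = set(origin_ids)
    dests: list[str] = []
    for taz in [s.taz_id for s in services] + list(extra_dest_tazs):
        if taz not in universe:
            raise ValueError(f"destination TAZ {taz!r} is not a known zone")
        if taz not in dests:
            dests.append(taz)
    return SamplingPlan(origin_ids=origin_ids, dest_ids=tuple(dests), K=K)


def full_grid_cells(n_origins: int, hours: int = HOURS_PER_WEEK) -> int:
    """Off-diagonal cell count of the full weekly grid: n x (n-1) x hours."""
    return n_origins * (n_origins - 1) * hours


def estimated_cell_count(n_origins: int, K: int) -> int:
    """Off-diagonal cell count of the reconstructed per-level tensor."""
    return n_origins * (n_origins - 1) * K


def reduction_factor(full_count: int, sample_size: int) -> float:
    """Fold reduction of measurements achieved by the sampling plan."""
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    return full_count / sample_size


def reported_fold(full_count: int, sample_size: int) -> int:
    """Fold reduction rounded to the nearest integer for reporting."""
    return round_half_up_int(reduction_factor(full_count, sample_size))


# ---------------------------------------------------------------------------
# sampling and reconstruction
# ---------------------------------------------------------------------------


def sample_travel_times(
    hourly: HourlyTravelTensor,
    clustering: CongestionClustering,
    plan: SamplingPlan,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate hourly minutes per (origin, destination, level) of the plan.

    The default statistic is the mean over the level's hours (median via
    ``aggregator="median"``).  Row count equals ``plan.sample_size``.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    d_pos = {t: i for i, t in enumerate(hourly.dest_ids)}
    missing = [d for d in plan.dest_ids if d not in d_pos]
    if missing:
        raise ValueError(f"plan destinations missing from hourly tensor: {missing}")
    o_pos = {t: i for i, t in enumerate(hourly.origin_ids)}
    oi = np.array([o_pos[t] for t in plan.origin_ids])
    di = np.array([d_pos[t] for t in plan.dest_ids])
    sub = hourly.minutes[np.ix_(oi, di, np.arange(HOURS_PER_WEEK))]
    frames = []
    for lvl in range(1, plan.K + 1):
        hrs = clustering.hours_of_level(lvl)
        if hrs.size == 0:
            raise ValueError(f"congestion level {lvl} has no hours")
        agg = sub[:, :, hrs].mean(axis=2) if aggregator == "mean" else np.median(
            sub[:, :, hrs], axis=2
        )
        o, d = np.meshgrid(np.arange(len(oi)), np.arange(len(di)), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "origin_taz": np.asarray(plan.origin_ids, dtype=object)[o.ravel()],
                    "dest_taz": np.asarray(plan.dest_ids, dtype=object)[d.ravel()],
                    "level": lvl,
                    "minutes": agg.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def estimate_full_tensor(
    sampled: pd.DataFrame,
    origin_ids: Sequence[str],
    K: int,
    free_flow: np.ndarray | None = None,
) -> TravelTimeTensor:
    """Reconstruct the complete per-level origin-destination matrix.

    Per level, ``minutes ~ alpha + beta * free_flow`` is fit by least squares
    on the sampled off-diagonal pairs and used to predict every cell.
    Predictions are clamped to the free-flow floor, sampled cells keep their
    measured values, and per-pair monotonicity across levels is enforced by
    pooled-adjacent-violators.  When no analytic ``free_flow`` matrix is
    supplied the level-1 sampled times are used (requires a plan whose
    destinations are all TAZs).
    """
    ids = list(origin_ids)
    n = len(ids)
    pos = {t: i for i, t in enumerate(ids)}
    oi = sampled["origin_taz"].map(pos).to_numpy()
    di = sampled["dest_taz"].map(pos).to_numpy()
    lv = sampled["level"].to_numpy()
    val = sampled["minutes"].to_numpy(dtype=float)

    if free_flow is None:
        lvl1 = lv == 1
        ff = np.full((n, n), np.nan)
        ff[oi[lvl1], di[lvl1]] = val[lvl1]
        np.fill_diagonal(ff, 0.0)
        if np.isnan(ff).any():
            raise ValueError(
                "no free-flow matrix supplied and level-1 samples do not cover "
                "all origin-destination pairs"
            )
    else:
        ff = np.asarray(free_flow, dtype=float)
        if ff.shape != (n, n):
            raise ValueError(f"free_flow must be {n}x{n}, got {ff.shape}")

    alpha = np.empty(K)
    beta = np.empty(K)
    minutes = np.empty((n, n, K))
    offdiag = oi != di
    for lvl in range(1, K + 1):
        sel = (lv == lvl) & offdiag
        x = ff[oi[sel], di[sel]]
        y = val[sel]
        if sel.sum() < 2 or np.ptp(x) == 0:
            raise ValueError(
                f"degenerate fit for level {lvl}: need >=2 distinct free-flow values"
            )
        b, a = np.polyfit(x, y, 1)
        alpha[lvl - 1], beta[lvl - 1] = a, b
        minutes[:, :, lvl - 1] = np.maximum(a + b * ff, ff)

    sampled_mask = np.zeros((n, n, K), dtype=bool)
    sampled_mask[oi, di, lv - 1] = True
    minutes[oi, di, lv - 1] = val
    for k in range(K):
        np.fill_diagonal(minutes[:, :, k], 0.0)
    minutes = isotonic_rows(minutes)
    return TravelTimeTensor(
        origin_ids=ids,
        minutes=minutes,
        free_flow=ff,
        K=K,
        alpha=alpha,
        beta=beta,
        sampled_mask=sampled_mask,
    )


def nearest_service_times(
    tensor: TravelTimeTensor, services: Sequence[ServiceFacility]
) -> NearestServiceTimes:
    """Minimum travel time from every origin to any service-hosting TAZ.

    Origins that host a service get 0 at every level (within-TAZ convention).
    """
    service_tazs = sorted({s.taz_id for s in services})
    missing = [t for t in service_tazs if t not in tensor.origin_ids]
    if missing:
        raise ValueError(f"service TAZs not covered by tensor: {missing}")
    cols = np.array([tensor.index_of(t) for t in service_tazs])
    sub = tensor.minutes[:, cols, :]  # (n, n_service_taz, K)
    arg = sub.argmin(axis=1)  # (n, K)
    shortest = np.take_along_axis(sub, arg[:, None, :], axis=1)[:, 0, :]
    nearest = np.asarray(service_tazs, dtype=object)[arg]
    return NearestServiceTimes(
        origin_ids=list(tensor.origin_ids),
        shortest_minutes=shortest,
        nearest_service_taz=nearest,
        K=tensor.K,
    )
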