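"""Seeded synthetic cities for dynamic spatial-temporal accessibility analysis.

A synthetic city stands in for the census / service-registry / travel-time-API
data the analysis normally consumes: traffic analysis zones (TAZs) on a planar
km grid, per-TAZ populations disaggregated by sociodemographic attribute,
a handful of centrally clustered service facilities, and an hour-of-week
travel-time tensor whose congestion structure follows a known (recorded)
regime profile so that downstream clustering and estimation can be scored
against ground truth.

Defaults emulate a large Latin-American city: 507 zones, ~2.26 million
residents, roughly half of them in low-income strata concentrated toward the
periphery, services concentrated in six central zones, and a weekly congestion
profile in which the second-highest of nine traffic levels alone covers 40 of
the 168 hours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from ._util import largest_remainder

HOURS_PER_WEEK = 168

# City-wide category counts shaped like the reference census marginals
# (total 2,258,823).  Stratum uses the six Colombian socioeconomic levels
# plus "N.D." (no data); Low = 1-2, Middle = 3-4, High = 5-6.
DEFAULT_TOTAL_POPULATION = 2_258_823

DEFAULT_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "stratum": {
        "1": 455_000,
        "2": 654_549,
        "3": 561_419,
        "4": 374_280,
        "5": 122_753,
        "6": 81_836,
        "N.D.": 8_986,
    },
    "ethnicity": {
        "Afrodescendent": 325_865,
        "Rrom": 102,
        "Indigenous": 11_112,
        "Islander/Raizal": 382,
        "Other": 1_890_491,
        "Palenque": 245,
        "N.D.": 30_626,
    },
    "education": {
        "Graduate degree": 72_441,
        "Bachelor's degree": 295_319,
        "Technical": 244_160,
        "Middle": 608_429,
        "High School": 337_065,
        "Primary": 468_206,
        "Pre-school": 36_294,
        "No data": 196_909,
    },
    "literacy": {
        "Literate": 2_043_041,
        "No literacy": 66_383,
        "N.A.": 121_140,
        "N.D.": 28_259,
    },
    "sex": {
        "Fem": 1_208_617,
        "Masc": 1_050_206,
    },
    "civil_status": {
        "Single": 821_536,
        "Married or cohabitation": 896_958,
        "Divorced or separated": 163_980,
        "Widow": 95_611,
        "N.A.": 254_492,
        "N.D.": 26_246,
    },
    "age_band": {
        "0-4": 121_140,
        "5-14": 279_387,
        "15-24": 363_311,
        "25-59": 1_118_758,
        "60-64": 112_947,
        "65-79": 199_180,
        "80+": 64_100,
    },
}

LOW_STRATA = ("1", "2")
HIGH_STRATA = ("5", "6")

# Nine ordered congestion regimes, free-flow (1.0) to peak.  Regime r of the
# weekly profile below maps to multiplier DEFAULT_REGIME_MULTIPLIERS[r].
DEFAULT_REGIME_MULTIPLIERS = (1.0, 1.12, 1.25, 1.4, 1.55, 1.7, 1.9, 2.15, 2.5)


def default_week_profile() -> np.ndarray:
    """Hour-of-week -> true congestion regime (0-based, 0 = free-flow).

    Weekdays carry a morning and evening peak (regime 8) with a long
    congested working plateau at regime 7, so the second-highest regime
    covers 8 h x 5 days = 40 of the 168 hours; weekends ramp to a milder
    midday plateau.  Hour 0 is Monday 00:00.
    """
    weekday = [0, 0, 0, 0, 1, 2, 5, 8, 8, 7, 7, 7, 7, 7, 7, 7, 7, 8, 8, 6, 5, 4, 2, 1]
    weekend = [0, 0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 6, 6, 6, 6, 6, 6, 5, 5, 4, 3, 2, 1, 0]
    return np.array(weekday * 5 + weekend * 2, dtype=np.int64)


class CityConfig(BaseModel):
    """Configuration of a synthetic city; the seed is mandatory."""

    n_taz: int = 507
    total_population: int = DEFAULT_TOTAL_POPULATION
    n_service_taz: int = 6
    n_services: int = 11
    cell_km: float = 0.66
    speed_kmh: float = 30.0
    access_min: float = 2.0
    regime_multipliers: tuple[float, ...] = DEFAULT_REGIME_MULTIPLIERS
    hour_regime: tuple[int, ...] | None = None  # default: default_week_profile()
    noise_sd: float = 0.05
    income_gradient: float = 2.0
    density_gradient: float = 1.3
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "CityConfig":
        for name in ("n_taz", "total_population", "n_service_taz", "n_services"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cell_km <= 0 or self.speed_kmh <= 0:
            raise ValueError("cell_km and speed_kmh must be positive")
        if self.access_min < 0 or self.noise_sd < 0:
            raise ValueError("access_min and noise_sd must be nonnegative")
        mults = np.asarray(self.regime_multipliers)
        if (mults < 1.0).any():
            raise ValueError("regime multipliers must be >= 1 (free-flow floor)")
        if self.hour_regime is not None:
            hr = np.asarray(self.hour_regime)
            if hr.size != HOURS_PER_WEEK:
                raise ValueError("hour_regime must cover all 168 hours")
            if hr.min() < 0 or hr.max() >= mults.size:
                raise ValueError("hour_regime indexes outside regime_multipliers")
        return self


@dataclass(frozen=True)
class TrafficAnalysisZone:
    """A traffic analysis zone: the unit of accessibility analysis."""

    taz_id: str
    centroid_xy: tuple[float, float]  # planar km
    polygon: tuple[tuple[float, float], ...] | None
    total_population: int

    def __post_init__(self) -> None:
        if self.total_population < 0:
            raise ValueError("total_population must be nonnegative")


@dataclass(frozen=True)
class ServiceFacility:
    service_id: str
    taz_id: str
    chairs: int


@dataclass
class HourlyTravelTensor:
    """Minutes from each origin TAZ to each destination TAZ for 168 hours.

    ``hour_regime`` / ``regime_multipliers`` record the generator's ground
    truth so clustering and estimation can be scored for recovery; they are
    ``None`` for tensors read back from disk.
    """

    origin_ids: list[str]
    dest_ids: list[str]
    minutes: np.ndarray  # (n_origin, n_dest, 168)
    free_flow: np.ndarray  # (n_origin, n_dest)
    hour_regime: np.ndarray | None = None
    regime_multipliers: np.ndarray | None = None

    def city_mean_profile(self) -> np.ndarray:
        """City-mean travel time per hour over off-diagonal pairs."""
        mask = ~np.equal.outer(
            np.asarray(self.origin_ids, dtype=object),
            np.asarray(self.dest_ids, dtype=object),
        )
        if not mask.any():
            raise ValueError("tensor has no off-diagonal pairs")
        return self.minutes[mask].mean(axis=0)


# ---------------------------------------------------------------------------
# zone / population / service generation
# ---------------------------------------------------------------------------


def _zone_layout(config: CityConfig, rng: np.random.Generator):
    """Roughly disc-shaped city of square grid cells, ids ordered center-out."""
    n = config.n_taz
    side = int(np.ceil(np.sqrt(n)))
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    cx = (ii.ravel() + 0.5 - side / 2.0) * config.cell_km
    cy = (jj.ravel() + 0.5 - side / 2.0) * config.cell_km
    dist = np.hypot(cx, cy)
    order = np.lexsort((np.arange(dist.size), dist))[:n]
    cx, cy = cx[order], cy[order]
    jitter = rng.uniform(-0.3, 0.3, size=(n, 2)) * config.cell_km
    centroids = np.column_stack([cx, cy]) + jitter
    half = config.cell_km / 2.0
    polygons = [
        (
            (x - half, y - half),
            (x + half, y - half),
            (x + half, y + half),
            (x - half, y + half),
            (x - half, y - half),
        )
        for x, y in zip(cx, cy)
    ]
    return centroids, polygons, np.hypot(cx, cy)


def _taz_populations(config: CityConfig, dist: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # density rises toward the periphery (outlying districts are the densest)
    dmax = dist.max() if dist.max() > 0 else 1.0
    base = 0.35 + config.density_gradient * dist / dmax
    weights = base * rng.lognormal(mean=0.0, sigma=0.25, size=dist.size)
    return largest_remainder(weights, config.total_population)


def _ipf(seed_matrix: np.ndarray, row_totals: np.ndarray, col_totals: np.ndarray,
         n_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Iterative proportional fitting of a nonnegative matrix to given margins."""
    m = seed_matrix.astype(float).copy()
    for _ in range(n_iter):
        rs = m.sum(axis=1, keepdims=True)
        m = np.where(rs > 0, m * (row_totals[:, None] / np.where(rs == 0, 1, rs)), 0.0)
        cs = m.sum(axis=0, keepdims=True)
        m = np.where(cs > 0, m * (col_totals[None, :] / np.where(cs == 0, 1, cs)), 0.0)
        if np.abs(m.sum(axis=1) - row_totals).max() < tol:
            break
    return m


def _attribute_table(
    attribute: str,
    categories: list[str],
    global_counts: np.ndarray,
    taz_pops: np.ndarray,
    tilt: np.ndarray | None,
) -> np.ndarray:
    """Integer counts (n_taz x n_cat) with rows summing exactly to TAZ totals."""
    shares = global_counts / global_counts.sum()
    seed = np.outer(taz_pops, shares)
    if tilt is not None:
        seed = seed * tilt
    col_targets = shares * taz_pops.sum()
    fitted = _ipf(seed, taz_pops.astype(float), col_targets)
    out = np.zeros_like(seed, dtype=np.int64)
    for t in range(taz_pops.size):
        out[t] = largest_remainder(fitted[t], int(taz_pops[t]))
    return out


def generate_city(config: CityConfig):
    """Generate zones, population marginals and services for a synthetic city.

    Returns ``(zones, marginals, services)`` where ``marginals`` is a long
    DataFrame with columns ``taz_id, attribute, category, count``.  Within
    every TAZ the category counts of each attribute sum exactly to the TAZ
    population.  The low-stratum share of a TAZ grows with its distance from
    the central service cluster (the configured income gradient), while the
    city-wide stratum marginals are preserved by proportional fitting.
    Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    centroids, polygons, dist = _zone_layout(config, rng)
    taz_ids = [f"T{k:03d}" for k in range(config.n_taz)]
    taz_pops = _taz_populations(config, dist, rng)

    zones = [
        TrafficAnalysisZone(
            taz_id=taz_ids[k],
            centroid_xy=(float(centroids[k, 0]), float(centroids[k, 1])),
            polygon=polygons[k],
            total_population=int(taz_pops[k]),
        )
        for k in range(config.n_taz)
    ]

    # services cluster in the most central zones (ids are ordered center-out)
    n_service_taz = min(config.n_service_taz, config.n_taz)
    service_taz_ids = taz_ids[:n_service_taz]
    services = [
        ServiceFacility(
            service_id=f"S{k:02d}",
            taz_id=service_taz_ids[k % n_service_taz],
            chairs=int(rng.integers(10, 31)),
        )
        for k in range(config.n_services)
    ]

    dmax = dist.max() if dist.max() > 0 else 1.0
    dnorm = dist / dmax
    rows = []
    for attribute, counts in DEFAULT_CATEGORY_COUNTS.items():
        categories = list(counts)
        global_counts = largest_remainder(
            np.array([counts[c] for c in categories], dtype=float),
            config.total_population,
        )
        tilt = None
        if attribute == "stratum" and config.n_taz > 1:
            g = config.income_gradient
            tilt = np.ones((config.n_taz, len(categories)))
            centered = dnorm - dnorm.mean()
            for j, cat in enumerate(categories):
                if cat in LOW_STRATA:
                    tilt[:, j] = np.exp(g * centered)
                elif cat in HIGH_STRATA:
                    tilt[:, j] = np.exp(-g * centered)
        table = _attribute_table(attribute, categories, global_counts, taz_pops, tilt)
        for j, cat in enumerate(categories):
            for t in range(config.n_taz):
                rows.append((taz_ids[t], attribute, cat, int(table[t, j])))

    marginals = pd.DataFrame(rows, columns=["taz_id", "attribute", "category", "count"])
    return zones, marginals, services


# ---------------------------------------------------------------------------
# hourly travel-time tensor
# ---------------------------------------------------------------------------


def free_flow_matrix(
    zones: Sequence[TrafficAnalysisZone],
    config: CityConfig,
    dest_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Free-flow minutes: Euclidean centroid distance / speed + access constant.

    Diagonal entries (within-TAZ trips) are 0 by convention: the TAZ is the
    accessibility unit and within-zone trips are treated as instantaneous.
    """
    xy = np.array([z.centroid_xy for z in zones])
    ids = [z.taz_id for z in zones]
    if dest_ids is None:
        dest_ids = ids
    didx = [ids.index(d) for d in dest_ids]
    dxy = xy[didx]
    dists = np.hypot(
        xy[:, 0][:, None] - dxy[:, 0][None, :],
        xy[:, 1][:, None] - dxy[:, 1][None, :],
    )
    ff = dists / config.speed_kmh * 60.0 + config.access_min
    diag = np.equal.outer(np.asarray(ids, dtype=object), np.asarray(dest_ids, dtype=object))
    ff[diag] = 0.0
    return ff


def generate_hourly_travel(
    zones: Sequence[TrafficAnalysisZone],
    config: CityConfig,
    dest_ids: Sequence[str] | None = None,
) -> HourlyTravelTensor:
    """Hour-of-week travel-time tensor with a known congestion-regime profile.

    ``minutes[o, d, h] = ff + (mult(h) - 1) * ff * eps`` where ``ff`` is the
    free-flow time, ``mult(h)`` the multiplier of hour ``h``'s regime and
    ``eps`` a mean-one lognormal noise term (sd ``config.noise_sd``) on the
    congestion increment.  Noise on the increment rather than the total keeps
    the free-flow floor exact for every pair and hour without clamping, so
    regression-based recovery of the multipliers is unbiased.  Restricting
    ``dest_ids`` (e.g. to service-hosting TAZs) avoids materialising the full
    43-million-cell weekly grid when only sampled destinations are needed.
    """
    if not zones:
        raise ValueError("zones must be nonempty")
    ids = [z.taz_id for z in zones]
    if dest_ids is None:
        dest_ids = ids
    regime = (
        np.asarray(config.hour_regime, dtype=np.int64)
        if config.hour_regime is not None
        else default_week_profile()
    )
    mults = np.asarray(config.regime_multipliers, dtype=float)
    if regime.max() >= mults.size:
        raise ValueError("hour regime indexes outside regime_multipliers")

    ff = free_flow_matrix(zones, config, dest_ids)
    hour_mult = mults[regime]  # (168,)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if config.noise_sd > 0:
        sd = config.noise_sd
        eps = rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=ff.shape + (HOURS_PER_WEEK,))
    else:
        eps = 1.0
    minutes = ff[..., None] * (1.0 + (hour_mult - 1.0)[None, None, :] * eps)
    return HourlyTravelTensor(
        origin_ids=ids,
        dest_ids=list(dest_ids),
        minutes=minutes,
        free_flow=ff,
        hour_regime=regime,
        regime_multipliers=mults,
    )


# ---------------------------------------------------------------------------
# I/O: GeoJSON + CSV artifacts
# ---------------------------------------------------------------------------


def write_zones_geojson(zones: Sequence[TrafficAnalysisZone], path: str | Path) -> None:
    features = []
    for z in zones:
        if z.polygon is not None:
            geometry = {
                "type": "Polygon",
                "coordinates": [[[round(x, 6), round(y, 6)] for x, y in z.polygon]],
            }
        else:
            geometry = {
                "type": "Point",
                "coordinates": [round(z.centroid_xy[0], 6), round(z.centroid_xy[1], 6)],
            }
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "taz_id": z.taz_id,
                    "total_population": z.total_population,
                    "centroid_x": round(z.centroid_xy[0], 6),
                    "centroid_y": round(z.centroid_xy[1], 6),
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")


def read_zones_geojson(path: str | Path) -> list[TrafficAnalysisZone]:
    doc = json.loads(Path(path).read_text())
    zones = []
    for feat in doc["features"]:
        geom, props = feat["geometry"], feat["properties"]
        if geom["type"] == "Polygon":
            polygon = tuple((float(x), float(y)) for x, y in geom["coordinates"][0])
        else:
            polygon = None
        zones.append(
            TrafficAnalysisZone(
                taz_id=props["taz_id"],
                centroid_xy=(float(props["centroid_x"]), float(props["centroid_y"])),
                polygon=polygon,
                total_population=int(props["total_population"]),
            )
        )
    return zones


def write_population_csv(marginals: pd.DataFrame, path: str | Path) -> None:
    marginals.to_csv(path, index=False)


def write_services_csv(services: Sequence[ServiceFacility], path: str | Path) -> None:
    pd.DataFrame(
        [(s.service_id, s.taz_id, s.chairs) for s in services],
        columns=["service_id", "taz_id", "chairs"],
    ).to_csv(path, index=False)


def read_services_csv(path: str | Path) -> list[ServiceFacility]:
    df = pd.read_csv(path, dtype={"taz_id": str})
    return [
        ServiceFacility(str(r.service_id), str(r.taz_id), int(r.chairs))
        for r in df.itertuples()
    ]


def write_travel_hourly_csv(tensor: HourlyTravelTensor, path: str | Path) -> None:
    """Long-format hourly travel times; diagonal (within-TAZ) rows omitted."""
    o_idx, d_idx, h_idx = np.meshgrid(
        np.arange(len(tensor.origin_ids)),
        np.arange(len(tensor.dest_ids)),
        np.arange(HOURS_PER_WEEK),
        indexing="ij",
    )
    origins = np.asarray(tensor.origin_ids, dtype=object)[o_idx.ravel()]
    dests = np.asarray(tensor.dest_ids, dtype=object)[d_idx.ravel()]
    keep = origins != dests
    df = pd.DataFrame(
        {
            "origin_taz": origins[keep],
            "dest_taz": dests[keep],
            "hour_of_week": h_idx.ravel()[keep],
            "minutes": np.round(tensor.minutes.ravel()[keep], 6),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_travel_hourly_csv(path: str | Path) -> HourlyTravelTensor:
    df = pd.read_csv(path, dtype={"origin_taz": str, "dest_taz": str})
    origins = sorted(df["origin_taz"].unique())
    dests = sorted(df["dest_taz"].unique())
    o_pos = {t: i for i, t in enumerate(origins)}
    d_pos = {t: i for i, t in enumerate(dests)}
    minutes = np.zeros((len(origins), len(dests), HOURS_PER_WEEK))
    minutes[
        df["origin_taz"].map(o_pos).to_numpy(),
        df["dest_taz"].map(d_pos).to_numpy(),
        df["hour_of_week"].to_numpy(),
    ] = df["minutes"].to_numpy()
    ff = minutes.min(axis=2)
    return HourlyTravelTensor(
        origin_ids=origins, dest_ids=dests, minutes=minutes, free_flow=ff
    )
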