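"""Cumulative-opportunity accessibility with sociodemographic disaggregation.

A zone is covered when its shortest car travel time to any service, under a
given congestion level, is within a threshold (default 20 minutes, inclusive).
Coverage is whole-TAZ: the zone's entire population counts as covered or not.
Results are disaggregated by sociodemographic category for the equity view,
traced over 10-minute threshold intervals (opportunity curves), and converted
to expected patient demand via a disease prevalence per 100,000 residents.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away, round_half_up_int
from .synthetic_city import TrafficAnalysisZone
from .travel_matrix import NearestServiceTimes

DEFAULT_THRESHOLD_MIN = 20.0
DEFAULT_PREVALENCE_PER_100K = 128.0

#: Grouping of the six socioeconomic stratum levels used in equity summaries.
STRATUM_GROUPS: dict[str, str] = {
    "1": "Low",
    "2": "Low",
    "3": "Middle",
    "4": "Middle",
    "5": "High",
    "6": "High",
    "N.D.": "N.D.",
}


@dataclass
class CoverageResult:
    """Population covered within the travel-time threshold at one level."""

    scenario: str
    level: int
    threshold_minutes: float
    covered_taz_ids: tuple[str, ...]
    covered_population: int
    total_population: int

    @property
    def percent(self) -> float:
        return percent(self.covered_population, self.total_population)


@dataclass
class DemandEstimate:
    """Expected patient count from prevalence applied to covered residents."""

    covered_population: int
    prevalence_per_100k: float

    @property
    def patients(self) -> int:
        return round_half_up_int(
            self.covered_population * self.prevalence_per_100k / 100_000.0
        )


def percent(covered: int, total: int) -> float:
    """Percentage to one decimal, half away from zero; NaN for empty totals."""
    if total == 0:
        return float("nan")
    return round_half_away(100.0 * covered / total, 1)


def variation(covered_a: int, covered_b: int, total: int) -> float:
    """Percentage-point change b - a, rounded once at the end.

    Rounding the difference of the unrounded percentages (rather than
    differencing rounded ones) reproduces the reported variation columns.
    """
    if total == 0:
        return float("nan")
    return round_half_away(100.0 * (covered_b - covered_a) / total, 1)


def covered_taz_mask(
    nearest: NearestServiceTimes, level: int, threshold: float
) -> np.ndarray:
    if not 1 <= level <= nearest.K:
        raise ValueError(f"level {level} outside 1..{nearest.K}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return nearest.shortest_minutes[:, level - 1] <= threshold


def coverage(
    nearest: NearestServiceTimes,
    zones: Sequence[TrafficAnalysisZone],
    level: int,
    threshold: float = DEFAULT_THRESHOLD_MIN,
    scenario: str = "",
) -> CoverageResult:
    """Cumulative-opportunity coverage: population within the threshold.

    A TAZ is covered iff its shortest time to a service at ``level`` is
    ``<= threshold`` (inclusive); covered population is the sum of whole-TAZ
    populations over the covered set.
    """
    pops = {z.taz_id: z.total_population for z in zones}
    mask = covered_taz_mask(nearest, level, threshold)
    covered_ids = tuple(t for t, m in zip(nearest.origin_ids, mask) if m)
    return CoverageResult(
        scenario=scenario,
        level=level,
        threshold_minutes=threshold,
        covered_taz_ids=covered_ids,
        covered_population=int(sum(pops[t] for t in covered_ids)),
        total_population=int(sum(pops[t] for t in nearest.origin_ids)),
    )


def equity_table(
    nearest_by_scenario: Mapping[str, NearestServiceTimes],
    zones: Sequence[TrafficAnalysisZone],
    marginals: pd.DataFrame,
    level: int,
    threshold: float = DEFAULT_THRESHOLD_MIN,
) -> pd.DataFrame:
    """Covered count and percent per sociodemographic category per scenario.

    Columns: ``attribute, category, total, share_of_total`` then per scenario
    ``covered_<s>`` and ``pct_<s>``; with two or more scenarios the last and
    first are compared in ``variation_count`` and ``pct_variation``.
    Categories with zero population get blank (NaN) percentages.
    """
    _check_marginals(zones, marginals)
    scen_names = list(nearest_by_scenario)
    totals = (
        marginals.groupby(["attribute", "category"], sort=False)["count"].sum().rename("total")
    )
    out = totals.reset_index()
    grand_total = sum(z.total_population for z in zones)
    out["share_of_total"] = [percent(t, grand_total) for t in out["total"]]

    for name in scen_names:
        nearest = nearest_by_scenario[name]
        mask = covered_taz_mask(nearest, level, threshold)
        covered_tazs = {t for t, m in zip(nearest.origin_ids, mask) if m}
        cov = (
            marginals[marginals["taz_id"].isin(covered_tazs)]
            .groupby(["attribute", "category"], sort=False)["count"]
            .sum()
            .reindex(totals.index, fill_value=0)
        )
        out[f"covered_{name}"] = cov.to_numpy()
        out[f"pct_{name}"] = [
            percent(c, t) for c, t in zip(out[f"covered_{name}"], out["total"])
        ]
        if (out["total"] == 0).any():
            warnings.warn(
                "categories with zero population: percent left blank", stacklevel=2
            )
    if len(scen_names) >= 2:
        a, b = scen_names[0], scen_names[-1]
        out["variation_count"] = out[f"covered_{b}"] - out[f"covered_{a}"]
        out["pct_variation"] = [
            variation(ca, cb, t)
            for ca, cb, t in zip(out[f"covered_{a}"], out[f"covered_{b}"], out["total"])
        ]
    return out


def _check_marginals(
    zones: Sequence[TrafficAnalysisZone], marginals: pd.DataFrame
) -> None:
    pops = pd.Series({z.taz_id: z.total_population for z in zones})
    sums = marginals.groupby(["attribute", "taz_id"])["count"].sum()
    for attribute, grp in sums.groupby(level="attribute"):
        per_taz = grp.droplevel("attribute").reindex(pops.index, fill_value=0)
        if not (per_taz == pops).all():
            bad = per_taz.index[per_taz != pops][0]
            raise ValueError(
                f"marginals for attribute {attribute!r} do not sum to the "
                f"TAZ population (first offender: {bad})"
            )


def opportunity_curve(
    nearest: NearestServiceTimes,
    zones: Sequence[TrafficAnalysisZone],
    marginals: pd.DataFrame,
    level: int,
    max_threshold: float = 60.0,
    step: float = 10.0,
) -> pd.DataFrame:
    """Coverage at threshold intervals, overall and by stratum group.

    Rows: one per (threshold, group) with group in {all, Low, Middle, High,
    N.D.}; coverage is non-decreasing in the threshold within each group.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    strat = marginals[marginals["attribute"] == "stratum"].copy()
    strat["group"] = strat["category"].map(STRATUM_GROUPS)
    group_by_taz = strat.groupby(["group", "taz_id"])["count"].sum()
    pops = {z.taz_id: z.total_population for z in zones}
    group_totals = group_by_taz.groupby(level="group").sum().to_dict()
    group_totals["all"] = sum(pops.values())

    thresholds = np.arange(step, max_threshold + step / 2, step)
    rows = []
    for thr in thresholds:
        mask = covered_taz_mask(nearest, level, float(thr))
        covered_tazs = {t for t, m in zip(nearest.origin_ids, mask) if m}
        rows.append(
            {
                "threshold_minutes": float(thr),
                "group": "all",
                "covered": int(sum(pops[t] for t in covered_tazs)),
                "total": group_totals["all"],
            }
        )
        for group in sorted(set(strat["group"])):
            sub = group_by_taz.loc[group]
            cov = int(sub[sub.index.isin(covered_tazs)].sum())
            rows.append(
                {
                    "threshold_minutes": float(thr),
                    "group": group,
                    "covered": cov,
                    "total": int(group_totals[group]),
                }
            )
    df = pd.DataFrame(rows)
    df["pct"] = [percent(c, t) for c, t in zip(df["covered"], df["total"])]
    return df


def estimate_patients(
    covered_population: int,
    prevalence_per_100k: float = DEFAULT_PREVALENCE_PER_100K,
) -> DemandEstimate:
    """Expected patients = covered population x prevalence / 100,000 (half-up)."""
    if covered_population < 0 or prevalence_per_100k < 0:
        raise ValueError("covered population and prevalence must be nonnegative")
    return DemandEstimate(
        covered_population=int(covered_population),
        prevalence_per_100k=float(prevalence_per_100k),
    )


def write_choropleth_geojson(
    nearest: NearestServiceTimes,
    zones: Sequence[TrafficAnalysisZone],
    level: int,
    threshold: float,
    path: str | Path,
    bin_minutes: float = 10.0,
) -> None:
    """Per-TAZ choropleth with shortest time, coverage flag and isochrone bin."""
    shortest = dict(zip(nearest.origin_ids, nearest.shortest_minutes[:, level - 1]))
    features = []
    for z in zones:
        t = float(shortest[z.taz_id])
        ring = z.polygon or (z.centroid_xy,)
        geometry = (
            {"type": "Polygon", "coordinates": [[[round(x, 6), round(y, 6)] for x, y in ring]]}
            if z.polygon
            else {"type": "Point", "coordinates": list(z.centroid_xy)}
        )
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "taz_id": z.taz_id,
                    "total_population": z.total_population,
                    "shortest_minutes": round(t, 3),
                    "covered": bool(t <= threshold),
                    "color_bin": int(np.ceil(t / bin_minutes)) if t > 0 else 0,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")
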