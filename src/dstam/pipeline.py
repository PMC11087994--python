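"""End-to-end orchestration, report artifacts, and the count-injection mode.

``run_pipeline`` executes the whole analysis on a synthetic city — simulate,
cluster the week's hours, sample travel times, reconstruct the full
per-level matrix, derive nearest-service times, compute coverage and equity
tables, and optimise siting of one and two new services — writing every
report artifact deterministically under a fixed seed.

``reproduce_reported_tables`` is the paper-count injection mode: it bypasses
simulation entirely and recomputes all percentages, variations and demand
estimates of the Cali 2020 haemodialysis case study from its reported counts
(shipped as CSV fixtures), exercising the arithmetic layer alone.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import accessibility as acc
from . import congestion, siting, synthetic_city, travel_matrix
from .accessibility import percent, variation
from .siting import GAConfig, SitingProblem
from .synthetic_city import CityConfig


class ScenarioSpec(BaseModel):
    """One measurement scenario: a label and a congestion scaling.

    ``congestion_scale`` rescales the excess of every regime multiplier over
    free-flow (1.0 keeps the baseline profile; 0.6 emulates a lighter-traffic
    week such as one under mobility restrictions).
    """

    label: str
    congestion_scale: float = 1.0


class RunConfig(BaseModel):
    """Full pipeline configuration; one seed drives every stochastic stage."""

    seed: int
    out_dir: str
    city: CityConfig | None = None
    K: int = 9
    threshold_minutes: float = 20.0
    curve_max_minutes: float = 60.0
    curve_step_minutes: float = 10.0
    prevalence_per_100k: float = 128.0
    scenarios: list[ScenarioSpec] = Field(
        default_factory=lambda: [
            ScenarioSpec(label="july", congestion_scale=1.0),
            ScenarioSpec(label="november", congestion_scale=0.6),
        ]
    )
    solver: str = "exhaustive"  # or "ga"
    ga_population_size: int = 100
    ga_generations: int = 200


def _scaled_city(config: CityConfig, scale: float, label: str) -> CityConfig:
    mults = tuple(1.0 + scale * (m - 1.0) for m in config.regime_multipliers)
    # distinct per-scenario noise stream, still a pure function of the seed
    sub_seed = int.from_bytes(
        hashlib.sha256(f"{config.seed}:{label}".encode()).digest()[:4], "big"
    ) % (2**31)
    return config.model_copy(update={"regime_multipliers": mults, "seed": sub_seed})


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (coverage per scenario, the
    equity table, opportunity curves, siting solutions and gains) and writes
    zones/population/services, per-scenario clustering and nearest-service
    tables, equity_table.csv, opportunity_curve.csv, choropleth.geojson,
    solution.json and run.log.  Re-running with the same config reproduces
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **params) -> None:
        blob = json.dumps(params, sort_keys=True, default=str)
        log_lines.append(f"{stage}\t{blob}")

    city_cfg = config.city or CityConfig(seed=config.seed)
    if config.city is None:
        city_cfg = city_cfg.model_copy(update={"seed": config.seed})
    zones, marginals, services = synthetic_city.generate_city(city_cfg)
    synthetic_city.write_zones_geojson(zones, out / "zones.geojson")
    synthetic_city.write_population_csv(marginals, out / "population.csv")
    synthetic_city.write_services_csv(services, out / "services.csv")
    log("simulate", n_taz=city_cfg.n_taz, total=city_cfg.total_population,
        seed=city_cfg.seed, files_sha=_sha(out / "zones.geojson"))

    service_tazs = sorted({s.taz_id for s in services})
    ff_full = synthetic_city.free_flow_matrix(zones, city_cfg)

    nearest_by_scenario: dict[str, travel_matrix.NearestServiceTimes] = {}
    results: dict = {"scenarios": {}}
    first_tensor = None
    for scen in config.scenarios:
        scfg = _scaled_city(city_cfg, scen.congestion_scale, scen.label)
        hourly = synthetic_city.generate_hourly_travel(zones, scfg, dest_ids=service_tazs)
        clustering = congestion.cluster_hours(hourly, K=config.K, seed=config.seed)
        clustering.to_frame().to_csv(out / f"clustering_{scen.label}.csv", index=False)
        plan = travel_matrix.build_sampling_plan(zones, services, K=clustering.K)
        sampled = travel_matrix.sample_travel_times(hourly, clustering, plan)
        tensor = travel_matrix.estimate_full_tensor(
            sampled, [z.taz_id for z in zones], clustering.K, free_flow=ff_full
        )
        nearest = travel_matrix.nearest_service_times(tensor, services)
        nearest.to_frame().to_csv(
            out / f"nearest_{scen.label}.csv", index=False, float_format="%.6f"
        )
        peak, free = clustering.K, 1
        cov_peak = acc.coverage(nearest, zones, peak, config.threshold_minutes, scen.label)
        cov_free = acc.coverage(nearest, zones, free, config.threshold_minutes, scen.label)
        curve = acc.opportunity_curve(
            nearest, zones, marginals, peak,
            config.curve_max_minutes, config.curve_step_minutes,
        )
        curve.insert(0, "scenario", scen.label)
        results["scenarios"][scen.label] = {
            "clustering": clustering,
            "sample_size": plan.sample_size,
            "coverage_peak": cov_peak,
            "coverage_free_flow": cov_free,
            "curve": curve,
        }
        nearest_by_scenario[scen.label] = nearest
        if first_tensor is None:
            first_tensor = tensor
            first_clustering = clustering
        log("scenario", label=scen.label, K=clustering.K,
            sample_size=plan.sample_size,
            coverage_peak=cov_peak.covered_population,
            coverage_free=cov_free.covered_population)

    peak = first_clustering.K
    equity = acc.equity_table(
        nearest_by_scenario, zones, marginals, peak, config.threshold_minutes
    )
    equity.to_csv(out / "equity_table.csv", index=False, float_format="%.1f")
    curves = pd.concat(
        [results["scenarios"][s.label]["curve"] for s in config.scenarios],
        ignore_index=True,
    )
    curves.to_csv(out / "opportunity_curve.csv", index=False, float_format="%.1f")
    first_label = config.scenarios[0].label
    acc.write_choropleth_geojson(
        nearest_by_scenario[first_label], zones, peak,
        config.threshold_minutes, out / "choropleth.geojson",
    )
    log("access", threshold=config.threshold_minutes, level=peak)

    # siting on the first (heavier-traffic) scenario at peak congestion
    solutions = {}
    gains = None
    for n_new in (1, 2):
        problem = SitingProblem(
            tensor=first_tensor, zones=zones, services=services,
            n_new=n_new, level=peak, threshold=config.threshold_minutes,
        )
        if config.solver == "ga":
            sol = siting.solve_ga(
                problem,
                GAConfig(
                    population_size=config.ga_population_size,
                    generations=config.ga_generations,
                    seed=config.seed,
                ),
            )
        else:
            sol = siting.solve_exhaustive(problem)
        solutions[n_new] = sol
        log("optimize", n_new=n_new, solver=config.solver,
            chosen=list(sol.taz_ids), objective=sol.objective, gain=sol.gain)
    problem_one = SitingProblem(
        tensor=first_tensor, zones=zones, services=services,
        n_new=1, level=peak, threshold=config.threshold_minutes,
    )
    gains = siting.predict_gains(problem_one, solutions[1], marginals, solutions[2])
    demand_one = acc.estimate_patients(
        solutions[1].gain, config.prevalence_per_100k
    )
    demand_two = acc.estimate_patients(
        solutions[2].gain, config.prevalence_per_100k
    )
    solution_doc = {
        "level": peak,
        "threshold_minutes": config.threshold_minutes,
        "baseline_covered": solutions[1].baseline,
        "one_site": {
            "chosen_taz_ids": list(solutions[1].taz_ids),
            "objective": solutions[1].objective,
            "gain": solutions[1].gain,
            "patients_in_gain": demand_one.patients,
        },
        "two_sites": {
            "chosen_taz_ids": list(solutions[2].taz_ids),
            "objective": solutions[2].objective,
            "gain": solutions[2].gain,
            "benefit_of_second": solutions[2].gain - solutions[1].gain,
            "patients_in_gain": demand_two.patients,
        },
    }
    (out / "solution.json").write_text(
        json.dumps(solution_doc, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    results.update(
        {
            "zones": zones, "marginals": marginals, "services": services,
            "equity_table": equity, "opportunity_curves": curves,
            "solutions": solutions, "gains": gains, "solution_doc": solution_doc,
        }
    )
    return results


def compare_scenarios(result_a: pd.DataFrame, result_b: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup percentage-point variation between two scenario tables.

    Each input must carry ``attribute, category, total`` and exactly one
    ``covered_*`` column over the same subgroup schema; the output adds
    ``variation_count`` and ``pct_variation`` (b minus a).
    """
    def covered_col(df: pd.DataFrame) -> str:
        cols = [c for c in df.columns if c.startswith("covered")]
        if len(cols) != 1:
            raise ValueError(f"expected exactly one covered_* column, got {cols}")
        return cols[0]

    ca, cb = covered_col(result_a), covered_col(result_b)
    key = ["attribute", "category", "total"]
    a = result_a[key + [ca]]
    b = result_b[key + [cb]]
    if not a[key].reset_index(drop=True).equals(b[key].reset_index(drop=True)):
        raise ValueError("scenario tables have mismatching subgroup schemas")
    merged = a.merge(b, on=key, validate="one_to_one")
    merged["pct_a"] = [percent(c, t) for c, t in zip(merged[ca], merged["total"])]
    merged["pct_b"] = [percent(c, t) for c, t in zip(merged[cb], merged["total"])]
    merged["variation_count"] = merged[cb] - merged[ca]
    merged["pct_variation"] = [
        variation(x, y, t) for x, y, t in zip(merged[ca], merged[cb], merged["total"])
    ]
    return merged


# ---------------------------------------------------------------------------
# paper-count injection mode
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dstam").joinpath("data", name)))


def load_reported_counts() -> pd.DataFrame:
    """Reported situational coverage counts of the Cali 2020 case study."""
    return pd.read_csv(_data_path("printed_counts.csv"))


def load_reported_predictions() -> pd.DataFrame:
    """Reported predicted coverage with one/two added services (overall and
    by stratum group)."""
    return pd.read_csv(_data_path("printed_predictions.csv"))


def load_reported_demand() -> pd.DataFrame:
    """Reported catchment populations of the proposed new services."""
    return pd.read_csv(_data_path("printed_demand.csv"))


def reproduce_reported_tables(
    prevalence_per_100k: float = 128.0, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Recompute every percentage of the case-study tables from raw counts.

    The injection mode: covered counts and subgroup totals are taken as
    given and only the arithmetic layer runs — percentages to one decimal,
    percentage-point variations (difference of unrounded percentages,
    rounded once), and prevalence-based patient demand.
    """
    counts = load_reported_counts()
    counts["pct_july"] = [
        percent(c, t) for c, t in zip(counts["covered_july"], counts["total"])
    ]
    counts["pct_november"] = [
        percent(c, t) for c, t in zip(counts["covered_november"], counts["total"])
    ]
    counts["variation_count"] = counts["covered_november"] - counts["covered_july"]
    counts["pct_variation"] = [
        variation(a, b, t)
        for a, b, t in zip(counts["covered_july"], counts["covered_november"], counts["total"])
    ]

    preds = load_reported_predictions()
    preds["pct_baseline"] = [
        percent(c, t) for c, t in zip(preds["baseline"], preds["total"])
    ]
    for col in ("add_one", "add_two"):
        preds[f"pct_{col}"] = [percent(c, t) for c, t in zip(preds[col], preds["total"])]
        preds[f"gain_{col}"] = preds[col] - preds["baseline"]
        preds[f"pct_variation_{col}"] = [
            variation(a, b, t)
            for a, b, t in zip(preds["baseline"], preds[col], preds["total"])
        ]
    preds["benefit_of_second"] = preds["add_two"] - preds["add_one"]

    demand = load_reported_demand()
    demand["prevalence_per_100k"] = prevalence_per_100k
    demand["patients"] = [
        acc.estimate_patients(c, prevalence_per_100k).patients
        for c in demand["covered_population"]
    ]

    tables = {"situational": counts, "predictions": preds, "demand": demand}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"reported_{name}.csv", index=False, float_format="%.1f")
    return tables


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
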