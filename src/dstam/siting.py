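"""Optimal siting of 1-2 new services: maximal covering location.

Given the reconstructed per-level travel-time tensor and the existing service
set, choose the one or two TAZs whose new services maximise the population
within the travel-time threshold.  An exhaustive enumerator provides the
global optimum at city scale for one or two sites; a seeded genetic algorithm
solves the same problem heuristically and is validated against the
enumerator.  Per-subgroup gains quantify who benefits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .accessibility import DEFAULT_THRESHOLD_MIN, percent
from .synthetic_city import ServiceFacility, TrafficAnalysisZone
from .travel_matrix import TravelTimeTensor


class GAConfig(BaseModel):
    """Genetic-algorithm settings; the seed is mandatory."""

    population_size: int = 100
    generations: int = 200
    tournament_size: int = 3
    mutation_rate: float = 0.1
    elitism: int = 1
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "GAConfig":
        if min(self.population_size, self.generations, self.tournament_size) <= 0:
            raise ValueError("population_size, generations, tournament_size must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        return self


@dataclass
class SitingProblem:
    """Maximal covering instance: where do 1-2 new services help most?"""

    tensor: TravelTimeTensor
    zones: Sequence[TrafficAnalysisZone]
    services: Sequence[ServiceFacility]
    n_new: int
    level: int
    threshold: float = DEFAULT_THRESHOLD_MIN
    candidates: tuple[str, ...] | None = None  # default: every TAZ

    def __post_init__(self) -> None:
        if self.n_new not in (1, 2):
            raise ValueError("n_new must be 1 or 2")
        if not 1 <= self.level <= self.tensor.K:
            raise ValueError(f"level {self.level} outside 1..{self.tensor.K}")
        if self.candidates is None:
            self.candidates = tuple(self.tensor.origin_ids)
        if not self.candidates:
            raise ValueError("candidate set must be nonempty")
        unknown = set(self.candidates) - set(self.tensor.origin_ids)
        if unknown:
            raise ValueError(f"unknown candidate TAZs: {sorted(unknown)}")

    # -- cached geometry of the instance ------------------------------------

    def _prepare(self):
        if getattr(self, "_cache", None) is not None:
            return self._cache
        ids = self.tensor.origin_ids
        pos = {t: i for i, t in enumerate(ids)}
        pops = np.array(
            [dict((z.taz_id, z.total_population) for z in self.zones)[t] for t in ids],
            dtype=np.int64,
        )
        mins = self.tensor.minutes[:, :, self.level - 1]
        service_cols = sorted({s.taz_id for s in self.services})
        if service_cols:
            existing = mins[:, [pos[t] for t in service_cols]].min(axis=1)
        else:
            existing = np.full(len(ids), np.inf)
        baseline_mask = existing <= self.threshold
        # cover_by_site[c, o]: candidate c's new service puts origin o in reach
        cand_idx = np.array([pos[t] for t in self.candidates])
        cover_by_site = (mins[:, cand_idx] <= self.threshold).T
        self._cache = (pops, baseline_mask, cover_by_site)
        return self._cache

    @property
    def baseline_covered(self) -> int:
        pops, baseline_mask, _ = self._prepare()
        return int(pops[baseline_mask].sum())


@dataclass
class SitingSolution:
    """Chosen TAZ set with objective and gain over the existing services."""

    taz_ids: tuple[str, ...]
    objective: int  # covered population with existing + new services
    baseline: int
    n_new: int
    level: int
    threshold: float
    log: list[tuple[int, int]] = field(default_factory=list)  # (generation, best)

    @property
    def gain(self) -> int:
        return self.objective - self.baseline


def coverage_with_sites(problem: SitingProblem, new_sites: Sequence[str]) -> int:
    """Covered population with services added at ``new_sites``.

    A TAZ counts as covered when either an existing service or one of the new
    sites is within the threshold; a new site always covers its own TAZ.
    """
    sites = list(new_sites)
    if len(sites) != problem.n_new or len(set(sites)) != len(sites):
        raise ValueError(f"expected {problem.n_new} distinct sites, got {sites}")
    unknown = set(sites) - set(problem.candidates)
    if unknown:
        raise ValueError(f"unknown site ids: {sorted(unknown)}")
    pops, baseline_mask, cover_by_site = problem._prepare()
    cand_pos = {t: i for i, t in enumerate(problem.candidates)}
    mask = baseline_mask.copy()
    for s in sites:
        mask |= cover_by_site[cand_pos[s]]
    return int(pops[mask].sum())


def solve_exhaustive(problem: SitingProblem, cap: int = 200_000) -> SitingSolution:
    """Global optimum by enumerating every candidate set of size ``n_new``.

    Ties are broken toward the lexicographically smallest TAZ-id set.  For
    507 zones and two sites this enumerates 128,271 pairs.
    """
    cands = sorted(problem.candidates)
    n_sets = comb(len(cands), problem.n_new)
    if n_sets > cap:
        raise ValueError(
            f"{n_sets} candidate sets exceed the cap ({cap}); use solve_ga"
        )
    pops, baseline_mask, cover_by_site = problem._prepare()
    cand_pos = {t: i for i, t in enumerate(problem.candidates)}
    order = np.array([cand_pos[t] for t in cands])
    cover = cover_by_site[order]  # rows in lexicographic candidate order
    popsf = pops.astype(np.float64)
    best_obj, best_set = -1, None
    if problem.n_new == 1:
        objs = ((cover | baseline_mask) @ popsf).astype(np.int64)
        i = int(objs.argmax())  # argmax returns the first (lex-smallest) max
        best_obj, best_set = int(objs[i]), (cands[i],)
    else:
        for i in range(len(cands) - 1):
            union = cover[i] | cover[i + 1 :] | baseline_mask
            objs = (union @ popsf).astype(np.int64)
            j = int(objs.argmax())
            if objs[j] > best_obj:
                best_obj, best_set = int(objs[j]), (cands[i], cands[i + 1 + j])
    return SitingSolution(
        taz_ids=best_set,
        objective=best_obj,
        baseline=problem.baseline_covered,
        n_new=problem.n_new,
        level=problem.level,
        threshold=problem.threshold,
    )


def solve_ga(problem: SitingProblem, config: GAConfig) -> SitingSolution:
    """Heuristic genetic algorithm for the maximal covering objective.

    Chromosome: a set of ``n_new`` distinct candidate TAZs.  Tournament
    selection (size 3), uniform site-swap crossover with duplicate repair,
    per-chromosome mutation replacing one site with a uniform random
    candidate, and single-individual elitism.  Deterministic under a fixed
    seed; returns the best individual found with a per-generation log.
    """
    rng = np.random.default_rng(config.seed)
    cands = sorted(problem.candidates)
    n_cand, n_new = len(cands), problem.n_new
    if n_cand < n_new:
        raise ValueError(f"need at least {n_new} candidates, have {n_cand}")
    pops, baseline_mask, cover_by_site = problem._prepare()
    cand_pos = {t: i for i, t in enumerate(problem.candidates)}
    order = np.array([cand_pos[t] for t in cands])
    cover = cover_by_site[order]
    popsf = pops.astype(np.float64)

    def fitness(pop_idx: np.ndarray) -> np.ndarray:
        mask = baseline_mask[None, :] | cover[pop_idx].any(axis=1)
        return (mask @ popsf).astype(np.int64)

    def repair(row: np.ndarray) -> np.ndarray:
        while len(set(row.tolist())) < n_new:
            dup = [i for i in range(1, n_new) if row[i] in row[:i]]
            row[dup[0]] = rng.integers(n_cand)
        return row

    pop = np.stack(
        [rng.choice(n_cand, size=n_new, replace=False) for _ in range(config.population_size)]
    )
    fit = fitness(pop)
    best_i = int(fit.argmax())
    best_set, best_fit = np.sort(pop[best_i]).copy(), int(fit[best_i])
    log = [(0, best_fit)]
    for gen in range(1, config.generations + 1):
        children = np.empty_like(pop)
        start = 0
        if config.elitism:
            children[:config.elitism] = best_set  # keep the incumbent
            start = config.elitism
        for i in range(start, config.population_size):
            t1 = rng.integers(config.population_size, size=config.tournament_size)
            t2 = rng.integers(config.population_size, size=config.tournament_size)
            p1 = pop[t1[fit[t1].argmax()]]
            p2 = pop[t2[fit[t2].argmax()]]
            take = rng.random(n_new) < 0.5
            child = np.where(take, p1, p2).copy()
            if rng.random() < config.mutation_rate:
                child[rng.integers(n_new)] = rng.integers(n_cand)
            children[i] = repair(child)
        pop = children
        fit = fitness(pop)
        gen_best = int(fit.argmax())
        if int(fit[gen_best]) > best_fit or (
            int(fit[gen_best]) == best_fit
            and tuple(np.sort(pop[gen_best])) < tuple(best_set)
        ):
            best_fit = int(fit[gen_best])
            best_set = np.sort(pop[gen_best]).copy()
        log.append((gen, best_fit))
    return SitingSolution(
        taz_ids=tuple(cands[i] for i in best_set),
        objective=best_fit,
        baseline=problem.baseline_covered,
        n_new=n_new,
        level=problem.level,
        threshold=problem.threshold,
        log=log,
    )


def predict_gains(
    problem: SitingProblem,
    solution: SitingSolution,
    marginals: pd.DataFrame,
    solution_two: SitingSolution | None = None,
) -> pd.DataFrame:
    """Per-subgroup covered counts and gains for a siting solution.

    One row per (attribute, category) plus an ``(overall, all)`` row.  With a
    second (two-site) solution supplied, adds its columns and the benefit of
    the second service (two-site gain minus one-site gain).
    """
    pops, baseline_mask, _ = problem._prepare()
    ids = problem.tensor.origin_ids

    def covered_sets(sol: SitingSolution) -> set[str]:
        _, base, cover_by_site = problem._prepare()
        cand_pos = {t: i for i, t in enumerate(problem.candidates)}
        mask = base.copy()
        for s in sol.taz_ids:
            mask |= cover_by_site[cand_pos[s]]
        return {t for t, m in zip(ids, mask) if m}

    baseline_tazs = {t for t, m in zip(ids, baseline_mask) if m}
    one_tazs = covered_sets(solution)
    groups = marginals.groupby(["attribute", "category"], sort=False)["count"]
    total = groups.sum()

    def cov_counts(taz_set: set[str]) -> pd.Series:
        sub = marginals[marginals["taz_id"].isin(taz_set)]
        return (
            sub.groupby(["attribute", "category"], sort=False)["count"]
            .sum()
            .reindex(total.index, fill_value=0)
        )

    out = total.rename("total").reset_index()
    base_cov = cov_counts(baseline_tazs)
    one_cov = cov_counts(one_tazs)
    out["baseline_covered"] = base_cov.to_numpy()
    out["covered_one"] = one_cov.to_numpy()
    out["gain_one"] = out["covered_one"] - out["baseline_covered"]
    if solution_two is not None:
        two_cov = cov_counts(covered_sets(solution_two))
        out["covered_two"] = two_cov.to_numpy()
        out["gain_two"] = out["covered_two"] - out["baseline_covered"]
        out["benefit_of_second"] = out["gain_two"] - out["gain_one"]

    grand_total = int(pops.sum())
    overall = {
        "attribute": "overall",
        "category": "all",
        "total": grand_total,
        "baseline_covered": problem.baseline_covered,
        "covered_one": solution.objective,
        "gain_one": solution.gain,
    }
    if solution_two is not None:
        overall["covered_two"] = solution_two.objective
        overall["gain_two"] = solution_two.gain
        overall["benefit_of_second"] = solution_two.gain - solution.gain
    out = pd.concat([pd.DataFrame([overall]), out], ignore_index=True)
    out["pct_with_new"] = [
        percent(c, t) for c, t in zip(out["covered_one"], out["total"])
    ]
    return out
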