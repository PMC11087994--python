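"""Sampling-plan arithmetic, tensor reconstruction and nearest-service times."""

import numpy as np
import pandas as pd
import pytest

import dstam
from dstam.synthetic_city import free_flow_matrix
from dstam.travel_matrix import (
    build_sampling_plan,
    estimate_full_tensor,
    estimated_cell_count,
    full_grid_cells,
    nearest_service_times,
    reduction_factor,
    reported_fold,
    sample_travel_times,
)


@pytest.mark.parametrize(
    "n_origins,n_dests,K,expected",
    [(507, 15, 9, 68_445), (507, 6, 9, 27_378), (1, 1, 1, 1)],
)
def test_sampling_plan_size_arithmetic(n_origins, n_dests, K, expected):
    assert n_origins * n_dests * K == expected  # the plan is a full product


def test_build_sampling_plan_collects_service_tazs(small_city):
    plan = build_sampling_plan(small_city["zones"], small_city["services"], K=9)
    hosts = {s.taz_id for s in small_city["services"]}
    assert set(plan.dest_ids) == hosts
    assert plan.sample_size == 20 * len(hosts) * 9
    extended = build_sampling_plan(
        small_city["zones"], small_city["services"], K=9,
        extra_dest_tazs=["T010", "T011"],
    )
    assert extended.sample_size == 20 * (len(hosts) + 2) * 9


def test_build_sampling_plan_requires_services(small_city):
    with pytest.raises(ValueError):
        build_sampling_plan(small_city["zones"], [], K=9)
    with pytest.raises(ValueError):
        build_sampling_plan(small_city["zones"], small_city["services"],
                            K=9, extra_dest_tazs=["nope"])


@pytest.mark.parametrize(
    "full,sample,ratio,fold",
    [(43_099_056, 68_445, 629.7, 630), (100, 100, 1.0, 1), (100, 4, 25.0, 25)],
)
def test_reduction_factor_and_reported_fold(full, sample, ratio, fold):
    assert reduction_factor(full, sample) == pytest.approx(ratio, abs=0.05)
    assert reported_fold(full, sample) == fold


def test_sampled_aggregate_is_the_level_mean(small_city, small_hourly, small_clustering):
    plan = build_sampling_plan(small_city["zones"], small_city["services"],
                               K=small_clustering.K)
    sampled = sample_travel_times(small_hourly, small_clustering, plan)
    assert len(sampled) == plan.sample_size
    row = sampled.iloc[37]
    o = small_hourly.origin_ids.index(row.origin_taz)
    d = small_hourly.dest_ids.index(row.dest_taz)
    hrs = small_clustering.hours_of_level(int(row.level))
    assert row.minutes == pytest.approx(small_hourly.minutes[o, d, hrs].mean())
    med = sample_travel_times(small_hourly, small_clustering, plan, aggregator="median")
    assert np.allclose(
        med[(med.origin_taz == row.origin_taz) & (med.dest_taz == row.dest_taz)
            & (med.level == row.level)]["minutes"],
        np.median(small_hourly.minutes[o, d, hrs]),
    )


def test_noise_free_sampling_equals_multiplier_times_free_flow():
    cfg = dstam.CityConfig(n_taz=5, total_population=5_000, n_service_taz=1,
                           n_services=1, noise_sd=0.0, seed=9)
    zones, _, services = dstam.generate_city(cfg)
    hourly = dstam.generate_hourly_travel(zones, cfg)
    clustering = dstam.cluster_hours(hourly, K=9, seed=0)
    plan = build_sampling_plan(zones, services, K=clustering.K)
    sampled = sample_travel_times(hourly, clustering, plan)
    mults = np.asarray(cfg.regime_multipliers)
    for row in sampled.itertuples():
        o = hourly.origin_ids.index(row.origin_taz)
        d = hourly.dest_ids.index(row.dest_taz)
        expected = hourly.free_flow[o, d] * mults[row.level - 1]
        assert row.minutes == pytest.approx(expected)


def test_estimated_cell_count_reference_scale():
    assert estimated_cell_count(507, 9) == 2_308_878  # ~2.3 million
    assert full_grid_cells(507) == 43_099_056


def test_noise_free_estimation_recovers_generator_exactly():
    cfg = dstam.CityConfig(n_taz=15, total_population=15_000, n_service_taz=3,
                           n_services=3, cell_km=2.0, noise_sd=0.0, seed=13)
    zones, _, services = dstam.generate_city(cfg)
    hourly = dstam.generate_hourly_travel(zones, cfg)
    clustering = dstam.cluster_hours(hourly, K=9, seed=0)
    plan = build_sampling_plan(zones, services, K=clustering.K)
    sampled = sample_travel_times(hourly, clustering, plan)
    ff = free_flow_matrix(zones, cfg)
    tensor = estimate_full_tensor(sampled, [z.taz_id for z in zones],
                                  clustering.K, free_flow=ff)
    mults = np.asarray(cfg.regime_multipliers)
    np.testing.assert_allclose(tensor.beta, mults, atol=1e-9)
    np.testing.assert_allclose(tensor.alpha, 0.0, atol=1e-7)
    # predictions are exact everywhere, not just at sampled cells
    expected = ff[:, :, None] * mults[None, None, :]
    np.testing.assert_allclose(tensor.minutes, expected, atol=1e-7)


def test_estimation_reproduces_sampled_cells_when_all_destinations_sampled(small_tensor, small_city, small_hourly, small_clustering):
    # plan destinations = all TAZs: sampled cells carry the aggregated values
    zones = small_city["zones"]
    plan = build_sampling_plan(
        zones, small_city["services"], K=small_clustering.K,
        extra_dest_tazs=[z.taz_id for z in zones],
    )
    sampled = sample_travel_times(small_hourly, small_clustering, plan)
    assert small_tensor.sampled_mask.all()
    for row in sampled.sample(40, random_state=0).itertuples():
        o = small_tensor.index_of(row.origin_taz)
        d = small_tensor.index_of(row.dest_taz)
        got = small_tensor.minutes[o, d, row.level - 1]
        # equal unless the per-pair monotonicity repair pooled this level
        level_slice = small_tensor.minutes[o, d, :]
        assert (np.diff(level_slice) >= -1e-9).all()
        if row.origin_taz != row.dest_taz:
            assert got == pytest.approx(row.minutes, rel=0.02)


def test_degenerate_fit_error_names_the_level(small_city):
    sampled = pd.DataFrame(
        {
            "origin_taz": ["T001", "T002"],
            "dest_taz": ["T000", "T000"],
            "level": [1, 1],
            "minutes": [5.0, 6.0],
        }
    )
    ff = np.ones((3, 3))  # constant free-flow: slope is unidentifiable
    with pytest.raises(ValueError, match="level 1"):
        estimate_full_tensor(sampled, ["T000", "T001", "T002"], 1, free_flow=ff)


def test_tensor_respects_floor_monotonicity_and_diagonal(small_tensor):
    ff = small_tensor.free_flow[:, :, None]
    assert (small_tensor.minutes >= ff - 1e-9).all()
    assert (np.diff(small_tensor.minutes, axis=2) >= -1e-9).all()
    n = len(small_tensor.origin_ids)
    diag = small_tensor.minutes[np.arange(n), np.arange(n), :]
    assert (diag == 0).all()


def test_nearest_service_times_match_brute_force(small_tensor, small_city, small_nearest):
    services = small_city["services"]
    hosts = sorted({s.taz_id for s in services})
    cols = [small_tensor.index_of(t) for t in hosts]
    for o in range(len(small_tensor.origin_ids)):
        for k in range(small_tensor.K):
            brute = min(small_tensor.minutes[o, c, k] for c in cols)
            assert small_nearest.shortest_minutes[o, k] == pytest.approx(brute)
    # service-hosting origins are at distance 0 for every level
    for t in hosts:
        o = small_nearest.origin_ids.index(t)
        assert (small_nearest.shortest_minutes[o] == 0).all()


def test_shortest_times_are_monotone_in_level(small_nearest):
    assert (np.diff(small_nearest.shortest_minutes, axis=1) >= -1e-9).all()


def test_pipeline_shortest_times_match_direct_hourly_aggregation(
    small_city, small_hourly, small_clustering, small_nearest
):
    # oracle: aggregate the hourly tensor per level directly and take the min
    hosts = sorted({s.taz_id for s in small_city["services"]})
    cols = [small_hourly.dest_ids.index(t) for t in hosts]
    for o in range(len(small_hourly.origin_ids)):
        for lvl in range(1, small_clustering.K + 1):
            hrs = small_clustering.hours_of_level(lvl)
            direct = min(small_hourly.minutes[o, c, hrs].mean() for c in cols)
            got = small_nearest.shortest_minutes[o, lvl - 1]
            assert got == pytest.approx(direct, rel=0.02, abs=1e-9)
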