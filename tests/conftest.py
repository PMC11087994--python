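import numpy as np
import pytest

import dstam
from dstam.synthetic_city import free_flow_matrix


@pytest.fixture(scope="session")
def small_config():
    # 20 zones spread over ~15 km so 20-min coverage is partial at peak
    return dstam.CityConfig(
        n_taz=20, total_population=40_000, n_service_taz=2, n_services=3,
        cell_km=3.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_city(small_config):
    zones, marginals, services = dstam.generate_city(small_config)
    return {
        "config": small_config,
        "zones": zones,
        "marginals": marginals,
        "services": services,
    }


@pytest.fixture(scope="session")
def small_hourly(small_city):
    return dstam.generate_hourly_travel(small_city["zones"], small_city["config"])


@pytest.fixture(scope="session")
def small_clustering(small_hourly):
    return dstam.cluster_hours(small_hourly, K=9, seed=0)


@pytest.fixture(scope="session")
def small_tensor(small_city, small_hourly, small_clustering):
    """Estimation bypassed: the plan samples every destination, so the tensor
    equals the per-level aggregate of the hourly tensor for sampled cells."""
    zones, services = small_city["zones"], small_city["services"]
    plan = dstam.build_sampling_plan(
        zones, services, K=small_clustering.K,
        extra_dest_tazs=[z.taz_id for z in zones],
    )
    sampled = dstam.sample_travel_times(small_hourly, small_clustering, plan)
    ff = free_flow_matrix(zones, small_city["config"])
    return dstam.estimate_full_tensor(
        sampled, [z.taz_id for z in zones], small_clustering.K, free_flow=ff
    )


@pytest.fixture(scope="session")
def small_nearest(small_tensor, small_city):
    return dstam.nearest_service_times(small_tensor, small_city["services"])


def make_flat_instance(n_taz: int, seed: int, level: int = 9, threshold: float = 30.0):
    """Small maximal-covering instance with an analytic (noise-free) tensor."""
    cfg = dstam.CityConfig(
        n_taz=n_taz, total_population=2_000 * n_taz, n_service_taz=2,
        n_services=2, cell_km=2.5, noise_sd=0.0, seed=seed,
    )
    zones, marginals, services = dstam.generate_city(cfg)
    ff = free_flow_matrix(zones, cfg)
    mults = np.asarray(cfg.regime_multipliers)
    minutes = ff[:, :, None] * mults[None, None, :]
    K = mults.size
    tensor = dstam.TravelTimeTensor(
        origin_ids=[z.taz_id for z in zones], minutes=minutes, free_flow=ff,
        K=K, alpha=np.zeros(K), beta=mults.copy(),
        sampled_mask=np.ones(minutes.shape, dtype=bool),
    )
    problem_kwargs = dict(
        tensor=tensor, zones=zones, services=services,
        level=level, threshold=threshold,
    )
    return zones, marginals, services, tensor, problem_kwargs
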