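import numpy as np
import pandas as pd
import pytest

import hemimorph as hm

TINY_REGIONS = ("REC", "MCG", "SPG", "STG", "TPOmid", "PCUN")


@pytest.fixture(scope="session")
def tiny_config() -> hm.GeneratorConfig:
    return hm.GeneratorConfig(
        n_female=2, n_male=2, n_regions_per_hemisphere=6,
        vertices_per_region=150, region_names=TINY_REGIONS, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_template(tiny_config):
    return hm.generate_surface(tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_template, tiny_config):
    return hm.generate_cohort(tiny_template, tiny_config)


@pytest.fixture(scope="session")
def tiny_parcellation(tiny_template):
    return hm.upsample(tiny_template, seed=11, target_per_hemisphere=24)


@pytest.fixture(scope="session")
def default_template():
    return hm.generate_surface(hm.GeneratorConfig(n_female=1, n_male=1, seed=5))


def random_density_pair(seed: int, n_mesh: int = 27):
    """Two random discrete distributions on a shared grid."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(1.0, 4.0, n_mesh)
    p = rng.random(n_mesh) + 1e-6
    q = rng.random(n_mesh) + 1e-6
    return (
        hm.RegionDensity(0, grid, p / p.sum()),
        hm.RegionDensity(1, grid, q / q.sum()),
    )
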