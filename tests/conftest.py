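import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from airwayrf import RunConfig, run_simulation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_result():
    """Full default activation on the coarse mesh (shared across tests)."""
    return run_simulation(RunConfig())


@pytest.fixture(scope="session")
def tiny_config():
    cfg = RunConfig()
    cfg.solver.refinement = "tiny"
    return cfg


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    """Full default activation on the tiny mesh (fast property checks)."""
    return run_simulation(tiny_config)


@pytest.fixture(scope="session")
def sector_mesh():
    from airwayrf import DeviceGeometry, build_sector_geometry, generate_mesh

    return generate_mesh(build_sector_geometry(DeviceGeometry()), "tiny")


@pytest.fixture()
def sigma_table():
    from airwayrf import MaterialTable

    return MaterialTable()


def sigma_for(mesh, table=None):
    """Per-element baseline conductivity from the subdomain tags."""
    from airwayrf import MaterialTable
    from airwayrf.geometry import SUBDOMAIN_MATERIAL

    table = table or MaterialTable()
    sigma = np.empty(mesh.num_elements)
    for sub, name in SUBDOMAIN_MATERIAL.items():
        sigma[mesh.elem_tag == int(sub)] = table[name].sigma0
    return sigma
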