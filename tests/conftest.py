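import numpy as np
import pytest

from nanoscint.atomic_data import (
    ElementRecord,
    Material,
    default_library,
    load_element_table,
    make_toy_tables,
)
from nanoscint.geometry import AssemblyConfig, Body, GeometryModel, build_code_a
from nanoscint.transport import BeamConfig, RunConfig, Simulator


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def toy_library(tmp_path_factory):
    """Toy analytic tables: a Zn-like element (Z=30, edge 9.5 keV) and a
    light element (Z=8, edge 0.5 keV)."""
    d = tmp_path_factory.mktemp("toy_tables")
    grid = list(np.geomspace(0.25, 15.0, 40))
    paths = make_toy_tables([(30, 9.5, 6.0), (8, 0.5, 10.0)], grid, d)
    return {rec.symbol: rec for rec in map(load_element_table, paths)}


@pytest.fixture(scope="session")
def code_a_model():
    return build_code_a(AssemblyConfig(code="A", n_zno=215, seed=1))


@pytest.fixture(scope="session")
def code_a_sim(code_a_model):
    """Compiled simulator for the full decorated-sphere assembly (shared:
    kernel compilation is the expensive step)."""
    return Simulator(code_a_model)


@pytest.fixture(scope="session")
def bare_sphere_model():
    """A single 80 nm SiO2 sphere in an air world (toy single-sphere
    geometry for estimator-equivalence checks)."""
    world = Body("sphere", (0.0, 0.0, 0.0), (500.0,), "air")
    sphere = Body("sphere", (0.0, 0.0, 0.0), (40.0,), "SiO2", 0)
    return GeometryModel(world=world, bodies=[sphere], label="bare_sphere")


@pytest.fixture(scope="session")
def bare_sphere_sim(bare_sphere_model):
    return Simulator(bare_sphere_model)


@pytest.fixture(scope="session")
def headline_run(code_a_sim):
    """The headline configuration: 10 keV beam on the 215-NP assembly,
    forced-interaction mode, 2x10^5 interacting histories.  Session-scoped
    so the partition, profile and conservation checks share one run."""
    beam = BeamConfig(energy=10.0, n_histories=200_000)
    run = RunConfig(seed=20260928, mode="forced")
    return code_a_sim.run(beam, run)
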