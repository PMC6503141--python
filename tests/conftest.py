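import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bonedyn import fem
from bonedyn.fixtures import (
    ToyFemurParams,
    make_beam_fixture,
    make_default_chain,
    make_default_muscle_set,
    make_toy_femur_mesh,
)

settings.register_profile(
    "bonedyn", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("bonedyn")


@pytest.fixture(scope="session")
def beam_small():
    """Small cantilever box: mesh, uniform material, assembly."""
    mesh, field = make_beam_fixture(10, 3, 3, E=10e9, nu=0.3)
    return mesh, field, fem.assemble(mesh, field)


@pytest.fixture(scope="session")
def beam_system(beam_small):
    """Clamped beam with a kinematic tip master."""
    mesh, field, asm = beam_small
    tip = fem.Coupling("tip", mesh.landmarks["tip_center"],
                       mesh.node_sets["tip"])
    return fem.SystemModel(asm, couplings=[tip],
                           fixed_dofs=fem.node_dofs(mesh.node_sets["clamp"]))


@pytest.fixture(scope="session")
def femur_coarse():
    params = ToyFemurParams(resolution=1)
    mesh, geo = make_toy_femur_mesh(params)
    return params, mesh, geo


@pytest.fixture(scope="session")
def squat_chain():
    chain = make_default_chain()
    return chain, make_default_muscle_set(chain)


@pytest.fixture(scope="session")
def pipeline_run():
    """One full toy-workflow execution shared by the acceptance checks."""
    from bonedyn.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report, profile, artifacts = run_pipeline()
    return report, profile, artifacts
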