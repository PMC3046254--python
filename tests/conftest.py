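import numpy as np
import pytest

from jointmorph.config import default_config
from jointmorph.meshing import attach_muscle_sets, phantom_to_mesh
from jointmorph.morphometry import locate_section_planes
from jointmorph.phantom import PhantomParams, generate_joint_phantom


@pytest.fixture(scope="session")
def default_volume():
    return generate_joint_phantom(PhantomParams())


@pytest.fixture(scope="session")
def simplified_volume():
    return generate_joint_phantom(PhantomParams(shape_simplification=1.0))


@pytest.fixture(scope="session")
def default_sections(default_volume):
    return locate_section_planes(default_volume)


@pytest.fixture(scope="session")
def joint_mesh(default_volume, default_sections):
    mesh = phantom_to_mesh(default_volume, default_sections.midline, target_edge=0.02)
    attach_muscle_sets(mesh)
    return mesh


@pytest.fixture(scope="session")
def stimuli_result():
    """Default end-to-end stimuli comparison, shared across tests."""
    from jointmorph.pipeline import run_stimuli_experiment
    return run_stimuli_experiment(default_config(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
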