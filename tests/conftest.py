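import sys
from pathlib import Path

import numpy as np
import pytest

REPO_ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO_ROOT / "scripts"))

from canopylight.synthetic import SynthParams, assemble_canopy, fixture_optics
from canopylight.tracer import KernelOptics, build_index, build_sensors


@pytest.fixture(scope="session")
def fixture_leaf_optics():
    """(phong, diffuse-equivalent, stem reflectance) packaged optics."""
    return fixture_optics()


@pytest.fixture(scope="session")
def kernel_optics(fixture_leaf_optics):
    phong, diffuse, stem = fixture_leaf_optics
    return (KernelOptics.from_optics(phong, stem),
            KernelOptics.from_optics(diffuse, stem))


@pytest.fixture(scope="session")
def single_plant_rig():
    """Seeded single-plant scene with sensors and index."""
    scene = assemble_canopy("single", 0.2, SynthParams(),
                            np.random.default_rng(0))
    sensors = build_sensors(scene)
    index = build_index(scene, extra_points=sensors.centers)
    return scene, index, sensors


@pytest.fixture(scope="session")
def grid3x3_rig():
    """Seeded 3x3 canopy with central-plant sensors and index."""
    scene = assemble_canopy("grid3x3", 0.2, SynthParams(),
                            np.random.default_rng(0))
    sensors = build_sensors(scene)
    index = build_index(scene, extra_points=sensors.centers)
    return scene, index, sensors
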