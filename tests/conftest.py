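"""Shared fixtures: small phantoms and cached Monte-Carlo runs."""

import numpy as np
import pytest

from ltu.phantom import (TissueProperties, VoxelGrid, preset,
                         build_layered_phantom, build_tumor_phantom)
from ltu.optics import BeamSpec, mc_fluence


@pytest.fixture(scope="session")
def chicken():
    return preset("chicken_breast_808")


@pytest.fixture(scope="session")
def absorber_only_props():
    """Purely absorbing medium for closed-form transport checks."""
    return TissueProperties(mu_a=100.0, mu_s=0.0, g=0.0, rho=1000.0,
                            cp=4000.0, kv=0.5, vs=1500.0)


@pytest.fixture(scope="session")
def scattering_slab(chicken):
    """Scattering-dominated slab, 12 mm deep at 0.5 mm voxels."""
    return build_layered_phantom([0.012], [chicken], dl=0.5e-3,
                                 lateral_extent=(0.016, 0.016))


@pytest.fixture(scope="session")
def pencil_beam():
    return BeamSpec(profile="flattop", diameter=1e-6, power_or_energy=1.0,
                    mode="pulsed")


@pytest.fixture(scope="session")
def slab_mc(scattering_slab):
    """One cached MC run in the scattering slab, reused across tests."""
    beam = BeamSpec(profile="gaussian", diameter=3e-3, power_or_energy=1e-3,
                    mode="pulsed")
    return mc_fluence(scattering_slab, beam, n_photons=100_000, seed=11)


@pytest.fixture(scope="session")
def small_tumor_grid(chicken):
    return build_tumor_phantom(
        5e-3, 3.2e-3, chicken, preset("tumor_mimic"), dl=0.5e-3,
        extent=(0.016, 0.016, 0.012))


@pytest.fixture
def uniform_grid(absorber_only_props):
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    return VoxelGrid(shape=(8, 8, 8), dl=0.5e-3, region_labels=labels,
                     props={0: absorber_only_props.replace(
                         mu_a=10.0, rho=1000.0, cp=4000.0, kv=0.5)})
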