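"""Shared phantoms, built once per session (construction dominates runtime)."""

import numpy as np
import pytest

import prostereo as ps


@pytest.fixture(scope="session")
def fat_tubule_phantom():
    """Fat-tubule phantom for Delesse validation (substantial Vv per compartment)."""
    spec = ps.PhantomSpec(
        block_edge_lengths=(1.0, 1.0, 1.0),
        voxel_size=0.004,
        tubule_count=15,
        tubule_lumen_radius=0.05,
        epithelium_thickness=0.02,
        tubule_length=0.7,
        rng_seed=2,
        placement_attempts=2_000_000,
    )
    return ps.build_phantom(spec)


@pytest.fixture(scope="session")
def thin_tubule_phantom():
    """Thin, long isotropic tubules: the regime where Lv = 2 Q_A holds tightly."""
    spec = ps.PhantomSpec(
        block_edge_lengths=(1.6, 1.6, 1.6),
        voxel_size=0.004,
        tubule_count=240,
        tubule_lumen_radius=0.006,
        epithelium_thickness=0.004,
        tubule_length=1.4,
        rng_seed=11,
        placement_attempts=2_000_000,
    )
    return ps.build_phantom(spec)


@pytest.fixture(scope="session")
def ball_phantom():
    """Sphere suspension (lumen balls in epithelial shells) for Sv validation."""
    spec = ps.PhantomSpec(
        block_edge_lengths=(1.0, 1.0, 1.0),
        voxel_size=0.004,
        tubule_count=60,
        tubule_lumen_radius=0.08,
        epithelium_thickness=0.02,
        inclusion_shape="ball",
        rng_seed=3,
        placement_attempts=2_000_000,
    )
    return ps.build_phantom(spec)


@pytest.fixture(scope="session")
def stroma_phantom_with_particles():
    """All-stroma block with Poisson-seeded mast cells and macrophages."""
    spec = ps.PhantomSpec(
        block_edge_lengths=(1.0, 1.0, 1.0),
        voxel_size=0.005,
        tubule_count=0,
        particle_density={"mast_cell": 150.0, "macrophage": 100.0},
        rng_seed=4,
    )
    return ps.build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
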