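"""Phantom generator: geometry, ground-truth oracles, determinism."""

import math

import numpy as np
import pytest

import prostereo as ps
from prostereo.phantom import (
    PackingError,
    analytic_truth,
    segment_distance,
    voxel_face_surface,
    SURFACE_CALIBRATION,
)


def test_empty_phantom_is_all_stroma():
    vol = ps.build_phantom(ps.PhantomSpec(tubule_count=0, voxel_size=0.01))
    gt = ps.true_quantities(vol)
    assert gt.vv == {"lumen": 0.0, "epithelium": 0.0, "stroma": 1.0}
    assert gt.lv == 0.0 and gt.sv == 0.0


def test_axis_aligned_cylinder_matches_closed_form():
    spec = ps.PhantomSpec(
        block_edge_lengths=(1.0, 1.0, 1.0),
        voxel_size=0.004,
        tubule_count=1,
        tubule_lumen_radius=0.05,
        epithelium_thickness=0.02,
        tubule_length=0.8,
        orientation_law=("fixed", (0.0, 0.0, 1.0)),
        rng_seed=1,
    )
    vol = ps.build_phantom(spec)
    gt = ps.true_quantities(vol)
    an = analytic_truth(spec)
    assert gt.vv["lumen"] == pytest.approx(an["vv_lumen"], rel=0.02)
    assert gt.vv["epithelium"] == pytest.approx(an["vv_epithelium"], rel=0.02)
    # centerline length oracle: 0.8 mm of axis in 1 mm^3
    assert gt.lv == pytest.approx(0.8, abs=1e-12)


def test_digital_ball_volume_converges_to_closed_form():
    # a hand-constructed lumen ball, independent of build_phantom
    vs = 0.004
    n = 250
    r = 0.2
    coords = (np.arange(n) + 0.5) * vs - 0.5
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    labels = np.where(X**2 + Y**2 + Z**2 <= r**2, ps.LUMEN, ps.STROMA).astype(np.uint8)
    vol = ps.LabelVolume(labels=labels, voxel_size=vs, centerlines=[], particles=[])
    gt = ps.true_quantities(vol)
    assert gt.vv["lumen"] == pytest.approx(4.0 / 3.0 * math.pi * r**3, rel=0.02)


def test_sphere_surface_oracle_calibration(ball_phantom):
    """Calibrated voxel-face counting recovers the analytic sphere surface."""
    gt = ps.true_quantities(ball_phantom)
    an = analytic_truth(ball_phantom.provenance)
    assert gt.sv == pytest.approx(an["sv"], rel=0.02)
    # and the raw face count shows the expected 3/2 overestimate
    raw = voxel_face_surface(ball_phantom.labels, ball_phantom.voxel_size)
    assert raw / ball_phantom.total_volume == pytest.approx(an["sv"] / SURFACE_CALIBRATION, rel=0.02)


def test_volume_fractions_partition_to_one(fat_tubule_phantom, ball_phantom):
    for vol in (fat_tubule_phantom, ball_phantom):
        gt = ps.true_quantities(vol)
        assert sum(gt.vv.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in gt.vv.values())


def test_particle_count_identity():
    vol = ps.build_phantom(ps.PhantomSpec(tubule_count=0, voxel_size=0.01, rng_seed=0))
    rng = np.random.default_rng(1)
    pts = [("mast_cell", rng.uniform(0, 1, 3)) for _ in range(50)]
    vol.particles.extend(pts)
    gt = ps.true_quantities(vol)
    assert gt.nv["mast_cell"] == pytest.approx(50.0, abs=1e-9)


def test_particle_seeding_poisson_mean_and_independence():
    base = ps.build_phantom(ps.PhantomSpec(tubule_count=0, voxel_size=0.02, rng_seed=0))
    v_st = base.stroma_volume()
    density = {"mast_cell": 200.0, "macrophage": 120.0}
    counts = np.array(
        [
            [
                sum(1 for c, _ in ps.seed_particles(base, density, s).particles if c == k)
                for k in ("mast_cell", "macrophage")
            ]
            for s in range(300)
        ],
        dtype=float,
    )
    for j, k in enumerate(("mast_cell", "macrophage")):
        lam = density[k] * v_st
        se = math.sqrt(lam / 300)
        assert counts[:, j].mean() == pytest.approx(lam, abs=3 * se)
    r = np.corrcoef(counts[:, 0], counts[:, 1])[0, 1]
    assert abs(r) < 3.0 / math.sqrt(300)


def test_seeded_particles_lie_in_stroma(fat_tubule_phantom):
    vol = ps.seed_particles(fat_tubule_phantom, {"mast_cell": 100.0}, 7)
    pts = np.array([p for _, p in vol.particles])
    assert np.all(vol.label_at(pts) == ps.STROMA)


def test_zero_density_seeds_nothing(fat_tubule_phantom):
    vol = ps.seed_particles(fat_tubule_phantom, {"mast_cell": 0.0}, 7)
    assert vol.particles == []


def test_build_is_deterministic():
    spec = ps.PhantomSpec(
        block_edge_lengths=(0.5, 0.5, 0.5),
        voxel_size=0.005,
        tubule_count=5,
        tubule_lumen_radius=0.02,
        epithelium_thickness=0.01,
        tubule_length=0.3,
        particle_density={"mast_cell": 100.0},
        rng_seed=42,
    )
    a = ps.build_phantom(spec)
    b = ps.build_phantom(spec)
    assert np.array_equal(a.labels, b.labels)
    assert len(a.particles) == len(b.particles)
    for (ca, pa), (cb, pb) in zip(a.particles, b.particles):
        assert ca == cb and np.array_equal(pa, pb)


def test_overlap_resolves_to_nearest_centerline():
    # two crossing axis-aligned tubes; the voxel on tube A's axis must keep A's label
    spec = ps.PhantomSpec(
        block_edge_lengths=(0.5, 0.5, 0.5),
        voxel_size=0.005,
        tubule_count=0,
        tubule_lumen_radius=0.03,
        epithelium_thickness=0.02,
        allow_overlap=True,
        rng_seed=0,
    )
    vol = ps.build_phantom(spec)
    import prostereo.phantom as ph

    dist = np.full(vol.labels.shape, np.inf, dtype=np.float32)
    a = (np.array([0.1, 0.25, 0.25]), np.array([0.4, 0.25, 0.25]))
    b = (np.array([0.25, 0.1, 0.21]), np.array([0.25, 0.4, 0.21]))  # 0.04 off in z
    for p0, p1 in (a, b):
        ph._paint_inclusion(vol.labels, dist, spec, p0, p1)
        vol.centerlines.append((p0, p1))
    # a point on tube A's axis inside the overlap zone
    lab = vol.label_at(np.array([[0.25, 0.25, 0.25]]))[0]
    assert lab == ps.LUMEN  # A's lumen wins over B's epithelium


def test_overdense_spec_raises_packing_error():
    spec = ps.PhantomSpec(
        block_edge_lengths=(0.5, 0.5, 0.5),
        voxel_size=0.005,
        tubule_count=200,
        tubule_lumen_radius=0.04,
        epithelium_thickness=0.02,
        tubule_length=0.3,
        rng_seed=0,
        placement_attempts=2000,
    )
    with pytest.raises(PackingError):
        ps.build_phantom(spec)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"voxel_size": -0.01},
        {"voxel_size": 0.003},  # does not divide the block edge
        {"tubule_lumen_radius": 0.3, "epithelium_thickness": 0.3},
        {"particle_density": {"mast_cell": -1.0}},
        {"orientation_law": "sideways"},
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        ps.PhantomSpec(block_edge_lengths=(1.0, 1.0, 1.0), **kwargs)


def test_segment_distance_basics():
    assert segment_distance([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]) == pytest.approx(1.0)
    assert segment_distance([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0]) == pytest.approx(1.0)
    # crossing segments touch
    assert segment_distance([-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)
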