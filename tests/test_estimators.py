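"""Stereological estimators: frozen scalar examples, counting rules, oracles."""

import numpy as np
import pytest
from scipy import ndimage

import prostereo as ps
from prostereo import estimators as est
from prostereo.sectioning import SectionField, SectionPlane


def _field(labels, pixel_size=0.01):
    return SectionField(
        labels=np.asarray(labels, dtype=np.uint8),
        pixel_size=pixel_size,
        plane=SectionPlane(normal=(0, 0, 1), offset=0.0),
        origin=(0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# scalar conversions (printed-table arithmetic)


@pytest.mark.parametrize(
    "weight,expected",
    [(423.08, 423.08), (0.0, 0.0), (87.60, 87.60)],
)
def test_volume_from_weight_specific_gravity_one(weight, expected):
    assert est.volume_from_weight(weight) == expected


def test_volume_from_weight_rejects_negative():
    with pytest.raises(ValueError):
        est.volume_from_weight(-1.0)


def test_absolute_volume_examples():
    # recomputed CBZ93 stroma cell of the published table
    v = est.absolute_volume(19.49, 260.24)
    assert v == pytest.approx(50.72, abs=0.01)
    assert v == pytest.approx(50.74, rel=0.001)
    assert est.absolute_volume(0.0, 99.0) == 0.0
    assert est.absolute_volume(100.0, 42.0) == 42.0
    with pytest.raises(ValueError):
        est.absolute_volume(120.0, 1.0)


@pytest.mark.parametrize("qa,expected", [(0.0, 0.0), (13.55, 27.10), (1.5, 3.0)])
def test_lv_is_twice_qa(qa, expected):
    assert est.lv_from_qa(qa) == pytest.approx(expected)


def test_total_length_and_reporting_scale():
    assert est.total_length(2.0, 10.0) == pytest.approx(20.0)
    # published rows satisfy L = Lv x Vt / 1000 on the table scale
    assert est.total_length(19.10, 423.08, paper_scale=True) == pytest.approx(8.07, rel=0.005)
    assert est.total_length(20.40, 231.00, paper_scale=True) == pytest.approx(4.70, rel=0.005)


def test_epithelial_surface_modes_differ_by_100():
    assert est.epithelial_surface(0.0, 100.0) == 0.0
    std = est.epithelial_surface(3.0, 200.0, paper_mode=False)
    paper = est.epithelial_surface(3.0, 200.0, paper_mode=True)
    assert std == pytest.approx(100.0 * paper)
    assert std == pytest.approx(600.0)


# ---------------------------------------------------------------------------
# Delesse area fractions


def test_vv_all_lumen_field_is_one():
    f = _field(np.full((20, 20), ps.LUMEN))
    assert est.vv_area_fraction(f, "lumen") == 1.0


def test_vv_half_epithelium_checkerboard():
    labels = np.indices((20, 20)).sum(axis=0) % 2
    f = _field(np.where(labels, ps.EPITHELIUM, ps.STROMA))
    assert est.vv_area_fraction(f, "epithelium") == 0.5


def test_vv_ignores_outside_pixels():
    labels = np.full((10, 10), ps.LUMEN)
    labels[:, 5:] = 0
    assert est.vv_area_fraction(_field(labels), ps.LUMEN) == 1.0


def test_vv_empty_field_set_raises():
    with pytest.raises(est.EmptyFieldSetError):
        est.vv_area_fraction(_field(np.zeros((5, 5))), "lumen")


# ---------------------------------------------------------------------------
# unbiased counting frame


def _disc(labels, r, c, rad, code=ps.EPITHELIUM):
    yy, xx = np.ogrid[: labels.shape[0], : labels.shape[1]]
    labels[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = code


def test_profile_touching_forbidden_edge_not_counted():
    labels = np.full((40, 40), ps.STROMA, dtype=np.uint8)
    _disc(labels, 20, 10, 4)  # straddles the frame's left edge at x=10
    f = _field(labels)
    frame = est.CountingFrame(origin=(0.10, 0.05), width=0.2, height=0.3)
    assert est.profile_count(f, frame, closing=False, min_area=1) == 0


def test_profile_touching_inclusion_edge_is_counted():
    labels = np.full((40, 40), ps.STROMA, dtype=np.uint8)
    _disc(labels, 20, 30, 4)  # straddles the right (inclusion) edge at x=30
    f = _field(labels)
    frame = est.CountingFrame(origin=(0.10, 0.05), width=0.2, height=0.3)
    assert est.profile_count(f, frame, closing=False, min_area=1) == 1


def test_profile_below_lower_edge_not_counted():
    labels = np.full((40, 40), ps.STROMA, dtype=np.uint8)
    _disc(labels, 5, 20, 4)  # straddles the lower edge at y=5
    f = _field(labels)
    frame = est.CountingFrame(origin=(0.10, 0.05), width=0.2, height=0.3)
    assert est.profile_count(f, frame, closing=False, min_area=1) == 0


def test_empty_field_counts_zero():
    f = _field(np.full((20, 20), ps.STROMA))
    assert est.profile_count(f, est.CountingFrame(width=0.1, height=0.1)) == 0


def test_frame_tiling_counts_each_profile_exactly_once(rng):
    """Exhaustive labelling oracle: sum of frame counts over a full tiling
    equals the number of distinct profiles, for arbitrary blob layouts."""
    for trial in range(3):
        labels = np.full((200, 200), ps.STROMA, dtype=np.uint8)
        for _ in range(45):
            _disc(labels, rng.integers(3, 197), rng.integers(3, 197), rng.integers(2, 9))
        f = _field(labels)
        mask = ndimage.binary_closing(
            labels == ps.EPITHELIUM, structure=np.ones((3, 3), bool)
        )
        cc, n_cc = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = np.bincount(cc.ravel())[1:]
        truth = int((sizes >= 4).sum())
        total = 0
        k = 0.5  # 50-pixel frames
        for fy in np.arange(0.0, 2.0, k):
            for fx in np.arange(0.0, 2.0, k):
                total += est.profile_count(
                    f, est.CountingFrame(origin=(fx, fy), width=k, height=k)
                )
        assert total == truth


def test_qa_pooled_is_ratio_of_sums():
    labels = np.full((40, 40), ps.STROMA, dtype=np.uint8)
    _disc(labels, 20, 20, 4)
    f = _field(labels)
    frame = est.CountingFrame(origin=(0.0, 0.0), width=0.4, height=0.4)
    qa, total, area = est.qa_pooled([f, f], frame)
    assert total == 2
    assert area == pytest.approx(2 * 0.4 * 0.4)
    assert qa == pytest.approx(2 / 0.32)


# ---------------------------------------------------------------------------
# cycloid intercepts


def test_single_crossing_of_straight_boundary():
    labels = np.full((100, 100), ps.EPITHELIUM, dtype=np.uint8)
    labels[:, :50] = ps.LUMEN
    f = _field(labels)
    grid = est.CycloidGrid(amplitude=0.06, spacing=(0.5, 0.5))
    origins = grid.arc_origins(f)
    # arcs exist and each spans the x = 0.5 boundary at most once
    assert len(origins) >= 1
    n_crossing_arcs = sum(
        1 for ox, _ in origins if ox < 0.5 < ox + np.pi * grid.amplitude
    )
    assert est.cycloid_intercepts(f, grid) == n_crossing_arcs


def test_no_lumen_means_no_intercepts(rng):
    labels = np.where(
        rng.random((60, 60)) < 0.3, ps.EPITHELIUM, ps.STROMA
    ).astype(np.uint8)
    f = _field(labels)
    assert est.cycloid_intercepts(f, est.CycloidGrid(amplitude=0.04)) == 0


def test_test_length_counts_only_tissue():
    labels = np.full((100, 100), ps.STROMA, dtype=np.uint8)
    f_full = _field(labels)
    labels0 = labels.copy()
    labels0[:, 50:] = 0
    f_half = _field(labels0)
    grid = est.CycloidGrid(amplitude=0.05, spacing=(0.12, 0.12))
    l_full = est.cycloid_test_length(f_full, grid)
    l_half = est.cycloid_test_length(f_half, grid)
    assert l_full > 0
    assert 0 < l_half < l_full


def test_sv_from_intercepts_formula():
    assert est.sv_from_intercepts(0, 10.0) == 0.0
    assert est.sv_from_intercepts(30, 10.0) == pytest.approx(6.0)
    assert est.sv_from_intercepts(30, 20.0, reference_area_fraction=0.5) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        est.sv_from_intercepts(3, 0.0)


def test_doubling_grid_density_doubles_length_not_sv(ball_phantom, rng):
    from prostereo.sectioning import sample_iur_plane, extract_section

    sparse = est.CycloidGrid(amplitude=0.04, spacing=(0.16, 0.12))
    dense = est.CycloidGrid(amplitude=0.04, spacing=(0.08, 0.12))
    I = {id(sparse): 0, id(dense): 0}
    L = {id(sparse): 0.0, id(dense): 0.0}
    for _ in range(40):
        plane = sample_iur_plane(ball_phantom, rng)
        f = extract_section(ball_phantom, plane)
        for g in (sparse, dense):
            I[id(g)] += est.cycloid_intercepts(f, g)
            L[id(g)] += est.cycloid_test_length(f, g)
    assert L[id(dense)] == pytest.approx(2.0 * L[id(sparse)], rel=0.1)
    sv_sparse = est.sv_from_intercepts(I[id(sparse)], L[id(sparse)])
    sv_dense = est.sv_from_intercepts(I[id(dense)], L[id(dense)])
    assert sv_dense == pytest.approx(sv_sparse, rel=0.15)


# ---------------------------------------------------------------------------
# optical disector counting rules


def _stack_with_particles(depths, xs=None):
    from prostereo.sectioning import DisectorStack

    n = len(depths)
    lookup = _field(np.full((50, 50), ps.STROMA))
    reference = _field(np.full((50, 50), ps.STROMA))
    particles = {
        "cls": np.array(["mast_cell"] * n, dtype=object),
        "x": np.array(xs if xs is not None else [0.25] * n),
        "y": np.full(n, 0.25),
        "depth": np.array(depths, dtype=float),
    }
    return DisectorStack(lookup=lookup, reference=reference, h=0.05, particles=particles)


def test_disector_depth_interval_half_open():
    stack = _stack_with_particles([0.0, 0.01, 0.05])
    frame = est.CountingFrame(origin=(0.0, 0.0), width=0.5, height=0.5)
    # in focus at look-up plane (depth 0) excluded; (0, h] counted
    assert est.disector_count(stack, "mast_cell", frame) == 2


def test_disector_frame_is_half_open_for_points():
    stack = _stack_with_particles([0.02, 0.02, 0.02], xs=[0.125, 0.25, 0.45])
    frame = est.CountingFrame(origin=(0.125, 0.0), width=0.125, height=0.5)
    # x = 0.125 on the inclusive lower-left origin counts, x = 0.25 on the
    # exclusion boundary does not, x = 0.45 is outside
    assert est.disector_count(stack, "mast_cell", frame) == 1


def test_nv_density_and_zero_volume_error(stroma_phantom_with_particles):
    from prostereo.sectioning import SectionPlane, make_disector

    vol = stroma_phantom_with_particles
    plane = SectionPlane(normal=(0, 0, 1), offset=-0.2)
    stack = make_disector(vol, plane, h=0.1)
    ox, oy = stack.lookup.origin
    frame = est.CountingFrame(origin=(-ox - 0.25, -oy - 0.25), width=0.5, height=0.5)
    nv = est.nv_optical_disector(stack, "mast_cell", frame)
    count = est.disector_count(stack, "mast_cell", frame)
    assert nv == pytest.approx(count / (0.25 * 0.1), rel=0.01)
    bad = est.CountingFrame(origin=(10.0, 10.0), width=0.01, height=0.01)
    with pytest.raises(ValueError):
        est.nv_optical_disector(_stack_with_particles([]), "mast_cell", bad)


# ---------------------------------------------------------------------------
# estimate records


def _example_raw():
    return {
        "pixels_lumen": 390.0,
        "pixels_epithelium": 430.0,
        "pixels_stroma": 180.0,
        "qa_count": 42.0,
        "qa_area_mm2": 3.5,
        "intercepts": 120.0,
        "test_length_mm": 60.0,
        "count_mast_cell": 12.0,
        "volume_mm3_mast_cell": 0.08,
    }


def test_record_derives_exactly_from_raw_counts():
    rec = est.build_estimate_record("C93-1", 423.08, _example_raw(), body_weight_g=345.0)
    assert rec.vt == 423.08
    assert sum(rec.vv.values()) == pytest.approx(1.0, abs=1e-12)
    assert sum(rec.v.values()) == pytest.approx(rec.vt, abs=1e-9)
    assert rec.q_a == pytest.approx(12.0)
    assert rec.lv == pytest.approx(24.0)
    assert rec.l_total == pytest.approx(24.0 * 423.08)
    assert rec.sv == pytest.approx(4.0)
    assert rec.nv["mast_cell"] == pytest.approx(150.0)
    assert rec.relative_weight == pytest.approx(423.08 / 345.0 * 100.0)


def test_record_missing_counts_raise():
    raw = _example_raw()
    del raw["qa_count"]
    with pytest.raises(KeyError):
        est.build_estimate_record("a", 100.0, raw)


def test_record_csv_roundtrip(tmp_path):
    rec = est.build_estimate_record("CBZ93-2", 260.24, _example_raw())
    path = tmp_path / "records.csv"
    est.records_to_csv([rec], str(path))
    back = est.records_from_csv(str(path))[0]
    assert back.animal_id == rec.animal_id
    assert back.vt == rec.vt
    assert back.vv == rec.vv
    assert back.nv == rec.nv
    assert back.raw == rec.raw
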