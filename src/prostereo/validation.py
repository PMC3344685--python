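"""Validation study battery: phantoms with known truth vs the estimators.

Each function runs one self-contained validation experiment — printed-table
arithmetic, Delesse unbiasedness, length and surface recovery, disector
conservation, statistics oracles, densitometry ordering, end-to-end effect
detection — and returns its headline numbers.  The experiments are used by
the acceptance test suite and by ``scripts/acceptance.py``.

The phantom geometries are fixed study materials (fixed construction
seeds), while every sampling decision is driven by the caller's seed.  The
validation phantoms sit in the regimes where each identity is informative:
fat tubules for volume fractions, thin long tubules for Lv = 2 Q_A (whose
finite-radius bias is ~ pi r / L), sphere suspensions for the cycloid
surface estimator, and pure stroma with Poisson particles for the disector.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd

from . import phantom as ph
from . import sectioning as sec
from . import estimators as est
from . import densitometry as dens
from . import stats as st
from .reference import REFERENCE_TABLE1, REFERENCE_TABLE2
from .study import default_config, simulate_cohort

# fixed study materials ------------------------------------------------------

FAT_TUBULE_SPEC = ph.PhantomSpec(
    block_edge_lengths=(1.0, 1.0, 1.0),
    voxel_size=0.004,
    tubule_count=15,
    tubule_lumen_radius=0.05,
    epithelium_thickness=0.02,
    tubule_length=0.7,
    rng_seed=2,
    placement_attempts=2_000_000,
)

THIN_TUBULE_SPEC = ph.PhantomSpec(
    block_edge_lengths=(1.6, 1.6, 1.6),
    voxel_size=0.004,
    tubule_count=240,
    tubule_lumen_radius=0.006,
    epithelium_thickness=0.004,
    tubule_length=1.4,
    rng_seed=11,
    placement_attempts=2_000_000,
)

BALL_SPEC = ph.PhantomSpec(
    block_edge_lengths=(1.0, 1.0, 1.0),
    voxel_size=0.004,
    tubule_count=60,
    tubule_lumen_radius=0.08,
    epithelium_thickness=0.02,
    inclusion_shape="ball",
    rng_seed=3,
    placement_attempts=2_000_000,
)

STROMA_SPEC = ph.PhantomSpec(
    block_edge_lengths=(1.0, 1.0, 1.0),
    voxel_size=0.005,
    tubule_count=0,
    rng_seed=4,
)

DISECTOR_INTENSITY = 150.0  # mm^-3, seeded Poisson intensity


# ---------------------------------------------------------------------------
# printed-table arithmetic


def volume_identity() -> dict:
    """Specific-gravity identity: volume column equals weight column."""
    devs = np.abs(
        REFERENCE_TABLE1["volume_mean"].to_numpy()
        - np.array([est.volume_from_weight(w) for w in REFERENCE_TABLE1["weight_mean"]])
    )
    return {"max_abs_dev": float(devs.max())}


def table2_consistency() -> dict:
    """V = Vv x Vt / 100 recomputed from the printed CBZ93 means (%)."""
    out = {}
    vt = float(REFERENCE_TABLE1.loc["CBZ93", "volume_mean"])
    for comp in ("stroma", "lumen", "epithelium"):
        r = REFERENCE_TABLE2.loc[("CBZ93", comp)]
        recomputed = est.absolute_volume(float(r["vv_mean"]), vt)
        out[comp] = abs(recomputed - float(r["v_mean"])) / float(r["v_mean"]) * 100.0
    return out


def table1_length_consistency() -> dict:
    """L = Lv x Vt on the tables' reporting scale, vs the printed L (%)."""
    out = {}
    for group in ("C93", "CBZ63", "CBZ93"):
        r = REFERENCE_TABLE1.loc[group]
        recomputed = est.total_length(
            float(r["lv_mean"]), float(r["volume_mean"]), paper_scale=True
        )
        out[group] = abs(recomputed - float(r["l_mean"])) / float(r["l_mean"]) * 100.0
    return out


# ---------------------------------------------------------------------------
# Delesse volume fractions


def delesse_validation(
    seed: int,
    n_replicates: int = 500,
    sections_per_replicate: int = 5,
    n_fields: int = 22,
    field_edge: float = 0.18,
    volume: ph.LabelVolume | None = None,
) -> dict:
    """Grand pooled Delesse estimate vs voxel truth, with Monte-Carlo SE.

    Each replicate pools ``sections_per_replicate`` IUR sections x
    ``n_fields`` systematic fields (inverse-sampling-fraction weighted);
    the grand ratio-of-sums over all replicates is compared with the
    phantom's voxel-counted volume fractions, with the SE obtained from the
    replicate spread by ratio-estimator linearization.
    """
    vol = ph.build_phantom(FAT_TUBULE_SPEC) if volume is None else volume
    gt = ph.true_quantities(vol)
    rng = np.random.default_rng(seed)
    X = {name: [] for name in ("lumen", "epithelium", "stroma")}
    Y = []
    codes = {"lumen": ph.LUMEN, "epithelium": ph.EPITHELIUM, "stroma": ph.STROMA}
    for _ in range(n_replicates):
        num = dict.fromkeys(X, 0.0)
        den = 0.0
        for _s in range(sections_per_replicate):
            plane = sec.sample_iur_plane(vol, rng)
            section = sec.extract_section(vol, plane)
            fields, info = sec.systematic_fields(
                section,
                n_fields=n_fields,
                field_edge=field_edge,
                rng=rng,
                allow_fewer=True,
                return_info=True,
            )
            w = info["weight"]
            for f in fields:
                for name, code in codes.items():
                    num[name] += w * float(np.count_nonzero(f.labels == code))
                den += w * float(np.count_nonzero(f.labels != ph.OUTSIDE))
        for name in X:
            X[name].append(num[name])
        Y.append(den)
    y = np.asarray(Y)
    out = {}
    for name in X:
        x = np.asarray(X[name])
        pooled = x.sum() / y.sum()
        resid = (x - pooled * y) / y.mean()
        se = resid.std(ddof=1) / math.sqrt(len(y))
        out[name] = {
            "pooled": float(pooled),
            "truth": float(gt.vv[name]),
            "se": float(se),
            "dev_in_se": float((pooled - gt.vv[name]) / se) if se > 0 else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# length density


def lv_validation(
    seed: int,
    n_sections: int = 150,
    n_fields: int = 22,
    field_edge: float = 0.7,
    frame_margin: float = 0.05,
    volume: ph.LabelVolume | None = None,
) -> dict:
    """Lv = 2 Q_A on the thin-tubule phantom vs centerline truth."""
    vol = ph.build_phantom(THIN_TUBULE_SPEC) if volume is None else volume
    gt = ph.true_quantities(vol)
    rng = np.random.default_rng(seed)
    total = 0.0
    area = 0.0
    for _ in range(n_sections):
        plane = sec.sample_iur_plane(vol, rng)
        section = sec.extract_section(vol, plane)
        fields, info = sec.systematic_fields(
            section,
            n_fields=n_fields,
            field_edge=field_edge,
            rng=rng,
            allow_fewer=True,
            return_info=True,
        )
        w = info["weight"]
        for f in fields:
            try:
                frame = est.CountingFrame.inset(f, frame_margin)
            except ValueError:
                continue
            total += w * est.profile_count(f, frame)
            area += w * est.frame_tissue_area(f, frame)
    lv_est = est.lv_from_qa(total / area)
    return {
        "lv_estimate": float(lv_est),
        "lv_truth": float(gt.lv),
        "rel_err_pct": float(100.0 * (lv_est / gt.lv - 1.0)),
    }


# ---------------------------------------------------------------------------
# surface density


def sv_validation(
    seed: int,
    n_sections: int = 150,
    n_fields: int = 22,
    field_edge: float = 0.6,
    volume: ph.LabelVolume | None = None,
) -> dict:
    """Cycloid Sv on the sphere suspension, plus the sv/vv = 3/r identity."""
    vol = ph.build_phantom(BALL_SPEC) if volume is None else volume
    gt = ph.true_quantities(vol)
    grid = est.CycloidGrid(amplitude=0.04, spacing=(0.08, 0.06))
    rng = np.random.default_rng(seed)
    intercepts = 0.0
    length = 0.0
    num_lu = 0.0
    den = 0.0
    for _ in range(n_sections):
        plane = sec.sample_iur_plane(vol, rng)
        section = sec.extract_section(vol, plane)
        fields, info = sec.systematic_fields(
            section,
            n_fields=n_fields,
            field_edge=field_edge,
            rng=rng,
            allow_fewer=True,
            return_info=True,
        )
        w = info["weight"]
        for f in fields:
            intercepts += w * est.cycloid_intercepts(f, grid)
            length += w * est.cycloid_test_length(f, grid)
            num_lu += w * float(np.count_nonzero(f.labels == ph.LUMEN))
            den += w * float(np.count_nonzero(f.labels != ph.OUTSIDE))
    sv_est = est.sv_from_intercepts(intercepts, length)
    vv_est = num_lu / den
    r = BALL_SPEC.tubule_lumen_radius
    return {
        "sv_estimate": float(sv_est),
        "sv_truth": float(gt.sv),
        "rel_err_pct": float(100.0 * (sv_est / gt.sv - 1.0)),
        "sv_over_vv": float(sv_est / vv_est),
        "three_over_r": float(3.0 / r),
        "ratio_rel_err_pct": float(100.0 * (sv_est / vv_est / (3.0 / r) - 1.0)),
    }


# ---------------------------------------------------------------------------
# optical disector


def disector_validation(
    seed: int,
    n_disectors: int = 110,
    frame_edge: float = 0.4,
    h: float = 0.06,
) -> dict:
    """Exact tiling conservation plus pooled Nv vs the Poisson intensity."""
    base = ph.build_phantom(STROMA_SPEC)
    vol = ph.seed_particles(base, {"mast_cell": DISECTOR_INTENSITY}, seed)
    n_seeded = len(vol.particles)

    # (a) full tiling of the block by disector boxes counts each particle once
    tile_h = 0.05
    tile_fe = 0.25
    counted = 0
    for k in range(int(round(1.0 / tile_h))):
        plane = sec.SectionPlane(normal=(0, 0, 1), offset=-0.5 + k * tile_h)
        stack = sec.make_disector(vol, plane, tile_h)
        ox, oy = stack.lookup.origin
        for i in range(4):
            for j in range(4):
                frame = est.CountingFrame(
                    origin=(-ox - 0.5 + i * tile_fe, -oy - 0.5 + j * tile_fe),
                    width=tile_fe,
                    height=tile_fe,
                )
                counted += est.disector_count(stack, "mast_cell", frame)

    # (b) pooled Nv at survey effort on IUR disector stacks
    rng = np.random.default_rng(seed + 1)
    total = 0
    volume_sampled = 0.0
    for _ in range(n_disectors):
        plane = sec.sample_iur_plane(vol, rng)
        support = sec.plane_support(vol, plane)
        if plane.offset + h > support:
            plane = dataclasses.replace(plane, offset=support - h)
        stack = sec.make_disector(vol, plane, h)
        ox, oy = stack.lookup.origin
        frame = est.CountingFrame(
            origin=(-ox - frame_edge / 2.0, -oy - frame_edge / 2.0),
            width=frame_edge,
            height=frame_edge,
        )
        total += est.disector_count(stack, "mast_cell", frame)
        x0, x1, y0, y1 = frame.pixel_box(stack.reference.pixel_size)
        area = (
            float(np.count_nonzero(stack.reference.labels[y0:y1, x0:x1] == ph.STROMA))
            * stack.reference.pixel_size**2
        )
        volume_sampled += area * stack.h
    nv_est = total / volume_sampled
    se = math.sqrt(max(total, 1)) / volume_sampled
    return {
        "tiling_counted": int(counted),
        "tiling_seeded": int(n_seeded),
        "nv_estimate": float(nv_est),
        "nv_intensity": DISECTOR_INTENSITY,
        "se": float(se),
        "dev_in_se": float((nv_est - DISECTOR_INTENSITY) / se),
    }


# ---------------------------------------------------------------------------
# statistics oracles


def stats_validation(seed: int, n_type1: int = 10_000) -> dict:
    """Brute-force oracles for the statistics layer.

    * exact Mann-Whitney p vs enumeration for every untied 3-vs-3 ranking,
    * balanced two-way ANOVA decomposition identity,
    * empirical type-I error of the pairwise t at alpha = 0.05.
    """
    # Mann-Whitney: the implementation vs direct enumeration of orderings
    values = [11, 25, 38, 44, 57, 60]
    max_dev = 0.0
    for combo in itertools.combinations(range(6), 3):
        a = [values[i] for i in combo]
        b = [values[i] for i in range(6) if i not in combo]
        res = st.mann_whitney(a, b, mode="exact")
        # oracle: enumerate all 20 equally likely group assignments directly
        from scipy.stats import rankdata

        ranks = rankdata(a + b)
        u_obs = ranks[:3].sum() - 6.0
        us = np.array(
            [sum(ranks[i] for i in c) - 6.0 for c in itertools.combinations(range(6), 3)]
        )
        p_oracle = float(np.mean(np.abs(us - 4.5) >= abs(u_obs - 4.5) - 1e-12))
        max_dev = max(max_dev, abs(res.p - p_oracle))

    # ANOVA decomposition identity on random balanced designs
    rng = np.random.default_rng(seed)
    max_resid = 0.0
    for _ in range(20):
        rows = []
        for t in ("control", "CBZ"):
            for a in (43, 63, 93):
                for y in rng.normal(10.0, 3.0, size=5):
                    rows.append({"treatment": t, "age": a, "y": y})
        res = st.two_way_anova(pd.DataFrame(rows), "y")
        ss = res["_ss"]
        max_resid = max(
            max_resid,
            abs(ss["total"] - (ss["A"] + ss["B"] + ss["AB"] + ss["error"])),
        )

    # type-I error of the pairwise t under the null
    rejections = 0
    for _ in range(n_type1):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        if st.student_t(x, y).significant:
            rejections += 1
    return {
        "mw_exact_max_abs_dev": float(max_dev),
        "anova_identity_max_resid": float(max_resid),
        "t_type1_rate_pct": 100.0 * rejections / n_type1,
    }


# ---------------------------------------------------------------------------
# densitometry


def iod_validation(seed: int, n_replicates: int = 100) -> dict:
    """Scale equivariance, monotonicity, and two-group mean ordering."""
    rng = np.random.default_rng(seed)
    img = rng.uniform(20.0, 200.0, size=(15, 15))
    roi = dens.NucleusROI(pixels=img, group="x")
    scale_dev = abs(
        dens.integrated_od(dens.NucleusROI(pixels=3.0 * img, group="x"), 600.0)
        - dens.integrated_od(roi, 200.0)
    )
    mono = all(
        dens.integrated_od(dens.NucleusROI(pixels=img * t1, group="x"), 200.0)
        > dens.integrated_od(dens.NucleusROI(pixels=img * t2, group="x"), 200.0)
        for t1, t2 in ((0.5, 0.8), (0.8, 1.0))
    )
    ordered = 0
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for sq in seeds:
        r = np.random.default_rng(sq)
        means = {}
        for grp, factor in (("control", 1.0), ("treated", 2.0)):
            image, centers = dens.render_nuclei_image(
                50, (160, 160), r, transmittance_factor=factor
            )
            rois = dens.sample_nuclei([(image, centers)], n_per_group=40, rng=r, group=grp)
            means[grp] = dens.group_iod(rois, incident_reference=230.0).mean
        ordered += means["treated"] < means["control"]
    return {
        "scale_equivariance_abs_dev": float(scale_dev),
        "monotone": bool(mono),
        "ordering_fraction_pct": 100.0 * ordered / n_replicates,
    }


# ---------------------------------------------------------------------------
# end-to-end effect detection


def power_validation(seed: int, n_studies: int = 200) -> dict:
    """Detection rate of the treated-vs-control 93-day weight decrease.

    Each simulated study draws the 6 x 5 cohort from the table-derived
    default configuration; the C93 vs CBZ93 comparison uses the pairwise
    Student t at alpha = 0.05 with the animal as the unit.
    """
    detected = 0
    base = int(np.random.default_rng(seed).integers(0, 2**31 - 10_000))
    for k in range(n_studies):
        frame, _ = simulate_cohort(default_config(base + k), with_specs=False)
        c = frame[frame["group"] == "C93"]["weight_mg"]
        t = frame[frame["group"] == "CBZ93"]["weight_mg"]
        if st.student_t(c, t).significant:
            detected += 1
    return {"detection_rate_pct": 100.0 * detected / n_studies}
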