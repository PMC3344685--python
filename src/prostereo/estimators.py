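"""Unbiased stereological estimators operating on sampled fields.

Every estimator is a pure function from raw counts (pixel tallies, profile
counts, line intercepts, disector tallies) and reference measures (areas,
test-line lengths, volumes) to a physical density or total:

* ``vv_area_fraction`` — Delesse principle, A_A = V_V, pooled as a
  ratio-of-sums over an animal's fields;
* ``profile_count`` / ``lv_from_qa`` — tubule length density Lv = 2 Q_A
  from profile counts in an unbiased counting frame with forbidden lines;
* ``cycloid_intercepts`` / ``sv_from_intercepts`` — surface density
  Sv = 2 I / L_T from cycloid test-line intercepts;
* ``nv_optical_disector`` — numerical density from optical-disector counts;
* the scalar conversions to absolute totals (V = Vv Vt / 100,
  L = Lv Vt, S = Sv Vt).

Totals follow the reporting conventions of the source tables when the
``paper_scale`` / ``paper_mode`` flags are set (lengths divided by 1000,
surfaces by 100); dimensionally standard values are always available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .phantom import LUMEN, EPITHELIUM, STROMA, OUTSIDE
from .sectioning import SectionField, DisectorStack

_EIGHT = np.ones((3, 3), dtype=int)


class EmptyFieldSetError(ValueError):
    pass


@dataclass(frozen=True)
class CountingFrame:
    """Unbiased 2D counting frame.

    ``origin`` is the (x, y) position of the lower-left corner in mm,
    relative to the field's lower-left corner; the right and upper edges are
    inclusion edges, the left and lower edges (with their extensions) are
    forbidden.  In pixel coordinates the rule is implemented half-open:
    an object is counted when it intersects the frame and has no pixel in
    ``{x < x0, y >= y0}`` (left edge and its upward extension) nor in
    ``{y < y0, x < x1}`` (lower edge and the downward extension at the
    lower-right corner), which counts each object exactly once under a
    frame tiling.
    """

    origin: tuple = (0.0, 0.0)
    width: float = 0.25
    height: float = 0.25

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame width and height must be positive")

    def pixel_box(self, pixel_size: float) -> tuple[int, int, int, int]:
        """(x0, x1, y0, y1) pixel-index bounds, half-open."""
        x0 = int(round(self.origin[0] / pixel_size))
        y0 = int(round(self.origin[1] / pixel_size))
        x1 = x0 + int(round(self.width / pixel_size))
        y1 = y0 + int(round(self.height / pixel_size))
        return x0, x1, y0, y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def inset(cls, field: SectionField, margin: float) -> "CountingFrame":
        """Frame filling a field up to a guard margin on every side."""
        w, h = field.extent
        if w <= 2 * margin or h <= 2 * margin:
            raise ValueError("margin leaves no frame area")
        return cls(origin=(margin, margin), width=w - 2 * margin, height=h - 2 * margin)


# ---------------------------------------------------------------------------
# Delesse volume fraction


def vv_area_fraction(
    fields: Iterable[SectionField] | SectionField, compartment: int | str
) -> float:
    """Pooled Delesse area fraction of a compartment over fields.

    Returns sum(compartment pixel area) / sum(in-block pixel area), pooled
    over all fields (ratio-of-sums, not mean-of-ratios).  ``compartment``
    may be a label code or one of ``"lumen" | "epithelium" | "stroma"``.
    """
    from .phantom import COMPARTMENTS

    code = COMPARTMENTS[compartment] if isinstance(compartment, str) else int(compartment)
    if isinstance(fields, SectionField):
        fields = [fields]
    num = 0
    den = 0
    for f in fields:
        num += int(np.count_nonzero(f.labels == code))
        den += int(np.count_nonzero(f.labels != OUTSIDE))
    if den == 0:
        raise EmptyFieldSetError("no in-block pixels in the supplied fields")
    return num / den


def volume_from_weight(fresh_weight_mg: float) -> float:
    """Prostate volume (mm^3) from fresh weight, at specific gravity 1.0.

    1.0 mg of fresh tissue corresponds to 1.0 mm^3.
    """
    if fresh_weight_mg < 0:
        raise ValueError("fresh weight must be nonnegative")
    return float(fresh_weight_mg) * 1.0


def absolute_volume(vv_percent: float, vt: float) -> float:
    """Absolute compartment volume V = Vv(%) x Vt / 100 (mm^3)."""
    if not 0.0 <= vv_percent <= 100.0:
        raise ValueError("vv_percent must lie in [0, 100]")
    return vv_percent * vt / 100.0


# ---------------------------------------------------------------------------
# profile counting and length density


def _component_flags(
    cc: np.ndarray, n_cc: int, frame_box: tuple[int, int, int, int]
) -> np.ndarray:
    """For each connected component, decide the counting-frame rule.

    Returns a boolean array of length ``n_cc + 1`` (index = component id);
    True when the component intersects the frame and avoids the forbidden
    region.
    """
    x0, x1, y0, y1 = frame_box
    ys, xs = np.nonzero(cc)
    ids = cc[ys, xs]
    inside = (xs >= x0) & (xs < x1) & (ys >= y0) & (ys < y1)
    forbidden = ((xs < x0) & (ys >= y0)) | ((ys < y0) & (xs < x1))
    has_inside = np.zeros(n_cc + 1, dtype=bool)
    has_forbidden = np.zeros(n_cc + 1, dtype=bool)
    np.logical_or.at(has_inside, ids[inside], True)
    np.logical_or.at(has_forbidden, ids[forbidden], True)
    return has_inside & ~has_forbidden


def profile_count(
    field: SectionField,
    frame: CountingFrame,
    closing: bool = True,
    min_area: int = 4,
) -> int:
    """Count glandular tubule profiles under the unbiased-frame rule.

    A profile is one 8-connected component of (lumen plus its epithelial
    ring).  Profiles intersecting the frame are counted unless they touch a
    forbidden line or its extensions; profiles touching only the inclusion
    (right/upper) edges are counted.

    Digital pre-processing: a 3x3 binary closing repairs the 1-pixel gaps
    that voxel aliasing opens in thin oblique profiles, and components
    smaller than ``min_area`` pixels are not identified as profiles (they
    are aliasing specks or sub-pixel tangential slivers; both choices were
    calibrated once against a continuum tube-plane intersection oracle).
    """
    mask = (field.labels == LUMEN) | (field.labels == EPITHELIUM)
    if not mask.any():
        return 0
    if closing:
        mask = ndimage.binary_closing(mask, structure=_EIGHT.astype(bool))
    cc, n_cc = ndimage.label(mask, structure=_EIGHT)
    flags = _component_flags(cc, n_cc, frame.pixel_box(field.pixel_size))
    if min_area > 1 and n_cc:
        sizes = np.bincount(cc.ravel(), minlength=n_cc + 1)
        flags &= sizes >= min_area
    return int(np.count_nonzero(flags[1:]))


def frame_tissue_area(field: SectionField, frame: CountingFrame) -> float:
    """In-block (tissue) area inside the frame, mm^2."""
    x0, x1, y0, y1 = frame.pixel_box(field.pixel_size)
    ny, nx = field.labels.shape
    sub = field.labels[max(y0, 0) : min(y1, ny), max(x0, 0) : min(x1, nx)]
    return float(np.count_nonzero(sub != OUTSIDE)) * field.pixel_size**2


def qa_pooled(
    fields: Sequence[SectionField], frame: CountingFrame
) -> tuple[float, int, float]:
    """Pooled profile density Q_A over fields (ratio-of-sums).

    Returns ``(q_a, total_count, total_area)`` where the denominator is the
    in-tissue area lying inside the counting frame of each field.
    """
    total = 0
    area = 0.0
    for f in fields:
        total += profile_count(f, frame)
        area += frame_tissue_area(f, frame)
    if area <= 0:
        raise EmptyFieldSetError("no tissue area under the counting frames")
    return total / area, total, area


def lv_from_qa(q_a: float) -> float:
    """Length density from profile density on IUR sections: Lv = 2 Q_A."""
    if q_a < 0:
        raise ValueError("q_a must be nonnegative")
    return 2.0 * q_a


def total_length(lv: float, vt: float, paper_scale: bool = False) -> float:
    """Total tubule length L = Lv x Vt (mm).

    With ``paper_scale`` the result is divided by 1000 to match the
    reporting convention of the source tables (which print L = Lv Vt /
    1000); without it the value is the dimensionally standard length in mm.
    """
    if lv < 0 or vt < 0:
        raise ValueError("lv and vt must be nonnegative")
    out = lv * vt
    return out / 1000.0 if paper_scale else out


# ---------------------------------------------------------------------------
# cycloid test grid and surface density


@dataclass(frozen=True)
class CycloidGrid:
    """A tiling of cycloid arcs used as test lines on vertical/IUR sections.

    Each arc is a half cycloid ``(a (t - sin t), a (1 - cos t))`` for
    ``t in [0, pi]``: width pi a, height 2 a, arc length 4 a; the minor
    (height) axis is aligned with the section's vertical axis, giving the
    sine-weighted line-orientation distribution required for unbiased
    surface estimation on vertical sections.  ``spacing`` is the (dx, dy)
    center-to-center distance of the arc lattice; halving it doubles the
    test-line length per area.

    ``boundary_sigma`` is the Gaussian pre-smoothing (in pixels) applied to
    the compartment indicator before its 0.5-level boundary is extracted
    for intercept counting: it reconstructs a sub-pixel boundary from the
    pixelated label image, suppressing the staircase jags that would
    otherwise be counted as spurious extra crossings.
    """

    amplitude: float = 0.04
    spacing: tuple = (0.18, 0.14)
    step_px: float = 0.4  # sampling step along the arc, in pixel units
    boundary_sigma: float = 0.8  # px; sub-pixel boundary reconstruction

    def __post_init__(self):
        if self.amplitude <= 0 or min(self.spacing) <= 0:
            raise ValueError("amplitude and spacing must be positive")

    @property
    def arc_length(self) -> float:
        return 4.0 * self.amplitude

    def arc_origins(self, field: SectionField) -> list:
        """Lower-left corners of arcs lying wholly inside the field."""
        w, h = field.extent
        aw, ah = math.pi * self.amplitude, 2.0 * self.amplitude
        out = []
        y = 0.5 * self.spacing[1]
        row = 0
        while y + ah <= h:
            x = 0.5 * self.spacing[0] * (1.0 + 0.5 * (row % 2))
            while x + aw <= w:
                out.append((x, y))
                x += self.spacing[0]
            y += self.spacing[1]
            row += 1
        return out

    def sample_arc(self, pixel_size: float) -> tuple[np.ndarray, np.ndarray, float]:
        """Points along one arc at uniform arc-length steps.

        Returns (x, y) offsets from the arc's lower-left corner and the
        arc-length step ds (mm).
        """
        a = self.amplitude
        ds = self.step_px * pixel_size
        n = max(8, int(math.ceil(self.arc_length / ds)))
        ds = self.arc_length / n
        s = (np.arange(n) + 0.5) * ds
        theta = 2.0 * np.arccos(np.clip(1.0 - s / (4.0 * a), -1.0, 1.0))
        x = a * (theta - np.sin(theta))
        y = a * (1.0 - np.cos(theta))
        return x, y, ds


def _grid_label_runs(field: SectionField, grid: CycloidGrid):
    """Yield (labels-along-arc, ds) for every arc of the grid in the field."""
    ps = field.pixel_size
    ny, nx = field.labels.shape
    ax, ay, ds = grid.sample_arc(ps)
    for ox, oy in grid.arc_origins(field):
        xs = ox + ax
        ys = oy + ay
        cols = np.clip((xs / ps).astype(int), 0, nx - 1)
        rows = np.clip((ys / ps).astype(int), 0, ny - 1)
        yield field.labels[rows, cols], ds


def _boundary_lines(field: SectionField, code: int, sigma: float):
    """Sub-pixel 0.5-level boundary of one compartment, as shapely lines.

    The binary indicator is Gaussian-smoothed before contour extraction so
    the boundary is a smooth curve through the pixelated interface rather
    than the staircase itself (coordinates in pixel units, (x, y)).
    """
    from shapely.geometry import LineString
    from skimage import measure

    mask = (field.labels == code).astype(float)
    if not mask.any():
        return []
    if sigma > 0:
        mask = ndimage.gaussian_filter(mask, sigma)
    return [
        LineString(np.column_stack([c[:, 1], c[:, 0]]))
        for c in measure.find_contours(mask, 0.5)
        if len(c) >= 2
    ]


def cycloid_intercepts(
    field: SectionField,
    grid: CycloidGrid,
    boundary: tuple[int, int] = (LUMEN, EPITHELIUM),
) -> int:
    """Number of transversal crossings between the grid and a boundary.

    The boundary of the first compartment in ``boundary`` is extracted at
    sub-pixel precision (smoothed 0.5-level contour) and its exact
    intersections with the cycloid polylines are counted; a crossing is
    accepted only when the labels flanking it along the arc belong to the
    boundary pair (so e.g. a lumen|stroma contact or the block edge is not
    scored).  Tangential touches resolve by crossing parity: a graze yields
    zero or two transversal intersections of the smooth contour.
    """
    from shapely.geometry import LineString
    from shapely.strtree import STRtree

    a, b = boundary
    lines = _boundary_lines(field, a, grid.boundary_sigma)
    if not lines:
        return 0
    tree = STRtree(lines)
    ps = field.pixel_size
    ny, nx = field.labels.shape
    ax, ay, _ = grid.sample_arc(ps)
    labels = field.labels
    count = 0
    for ox, oy in grid.arc_origins(field):
        xs = (ox + ax) / ps
        ys = (oy + ay) / ps
        arc = LineString(np.column_stack([xs, ys]))
        for idx in tree.query(arc):
            inter = lines[int(idx)].intersection(arc)
            if inter.is_empty:
                continue
            if inter.geom_type == "Point":
                pts = [inter]
            else:
                pts = [g for g in getattr(inter, "geoms", []) if g.geom_type == "Point"]
            for p in pts:
                i = int(np.argmin((xs - p.x) ** 2 + (ys - p.y) ** 2))
                i0, i1 = max(0, i - 4), min(len(xs) - 1, i + 4)
                la = labels[
                    min(max(int(ys[i0]), 0), ny - 1), min(max(int(xs[i0]), 0), nx - 1)
                ]
                lb = labels[
                    min(max(int(ys[i1]), 0), ny - 1), min(max(int(xs[i1]), 0), nx - 1)
                ]
                if {int(la), int(lb)} <= {a, b}:
                    count += 1
    return count


def cycloid_test_length(field: SectionField, grid: CycloidGrid) -> float:
    """Test-line length lying over tissue (in-block pixels), mm."""
    length = 0.0
    for labels, ds in _grid_label_runs(field, grid):
        length += float(np.count_nonzero(labels != OUTSIDE)) * ds
    return length


def sv_from_intercepts(
    total_intercepts: int,
    total_test_length: float,
    reference_area_fraction: float = 1.0,
) -> float:
    """Surface density Sv = 2 I / L_T (mm^-1).

    ``total_test_length`` is the test-line length over the reference space;
    if only the full grid length is known, ``reference_area_fraction``
    rescales it.
    """
    length = total_test_length * reference_area_fraction
    if length <= 0:
        raise ValueError("total test-line length over the reference space is zero")
    return 2.0 * total_intercepts / length


def epithelial_surface(sv: float, vt: float, paper_mode: bool = True) -> float:
    """Total epithelial surface from Sv and Vt.

    ``paper_mode`` follows the source tables' reporting convention
    S = Sv x Vt / 100; the dimensionally standard S = Sv x Vt (mm^2) is
    returned when it is off.  The two modes differ by exactly 100x.
    """
    if sv < 0 or vt < 0:
        raise ValueError("sv and vt must be nonnegative")
    out = sv * vt
    return out / 100.0 if paper_mode else out


# ---------------------------------------------------------------------------
# optical disector


def disector_count(
    stack: DisectorStack, particle_class: str, frame: CountingFrame
) -> int:
    """Particles counted by the optical-disector rule.

    The counting point of a (point) particle is its center; it is counted
    when its depth lies strictly below the look-up plane and at most at the
    reference plane (half-open interval ``(0, h]``) and its lateral position
    falls in the counting frame under the forbidden-line rule (half-open
    rectangle for point particles).  Particles in focus exactly at the
    look-up plane are excluded.
    """
    p = stack.particles
    lookup = stack.lookup
    ox, oy = lookup.origin
    x0 = ox + frame.origin[0]
    y0 = oy + frame.origin[1]
    sel = (
        (p["cls"] == particle_class)
        & (p["depth"] > 0.0)
        & (p["depth"] <= stack.h)
        & (p["x"] >= x0)
        & (p["x"] < x0 + frame.width)
        & (p["y"] >= y0)
        & (p["y"] < y0 + frame.height)
    )
    return int(np.count_nonzero(sel))


def nv_optical_disector(
    stack: DisectorStack,
    particle_class: str,
    frame: CountingFrame,
    reference_label: int = STROMA,
) -> float:
    """Numerical density (mm^-3 of reference compartment) by optical disector.

    Nv = scored particles / (sampled reference area x disector height),
    with the reference area delineated on the reference section inside the
    counting frame (matching the practice of multiplying delineated areas
    by section thickness).
    """
    count = disector_count(stack, particle_class, frame)
    x0, x1, y0, y1 = frame.pixel_box(stack.reference.pixel_size)
    ny, nx = stack.reference.labels.shape
    sub = stack.reference.labels[max(y0, 0) : min(y1, ny), max(x0, 0) : min(x1, nx)]
    area = float(np.count_nonzero(sub == reference_label)) * stack.reference.pixel_size**2
    volume = area * stack.h
    if volume <= 0:
        raise ValueError("disector reference volume is zero")
    return count / volume


# ---------------------------------------------------------------------------
# per-animal estimate record


@dataclass
class EstimateRecord:
    """One animal's estimates together with the raw counts that produced them.

    All derived fields reproduce exactly from ``raw`` (pixel tallies,
    profile counts, intercepts, disector tallies with their reference
    measures); lengths are stored in mm and surfaces in mm^2 (scaling to
    the source tables' conventions happens at reporting time).
    """

    animal_id: str
    fresh_weight_mg: float
    body_weight_g: float | None
    vt: float
    vv: dict
    v: dict
    q_a: float
    lv: float
    l_total: float
    sv: float
    s_total: float
    nv: dict
    raw: dict = field(default_factory=dict)

    @property
    def relative_weight(self) -> float | None:
        """Prostate weight per 100 g body weight (mg / 100 g b.w.)."""
        if self.body_weight_g is None:
            return None
        return self.fresh_weight_mg / self.body_weight_g * 100.0

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "fresh_weight_mg": self.fresh_weight_mg,
            "body_weight_g": self.body_weight_g,
            "vt": self.vt,
            "q_a": self.q_a,
            "lv": self.lv,
            "l_total": self.l_total,
            "sv": self.sv,
            "s_total": self.s_total,
        }
        for k, val in self.vv.items():
            row[f"vv_{k}"] = val
        for k, val in self.v.items():
            row[f"v_{k}"] = val
        for k, val in self.nv.items():
            row[f"nv_{k}"] = val
        for k, val in self.raw.items():
            row[f"raw_{k}"] = val
        return row

    @classmethod
    def from_row(cls, row: dict) -> "EstimateRecord":
        vv = {k[3:]: float(v) for k, v in row.items() if k.startswith("vv_")}
        v = {
            k[2:]: float(val)
            for k, val in row.items()
            if k.startswith("v_") and not k.startswith("vv_")
        }
        nv = {k[3:]: float(val) for k, val in row.items() if k.startswith("nv_")}
        raw = {k[4:]: float(val) for k, val in row.items() if k.startswith("raw_")}
        body = row.get("body_weight_g")
        if body is not None and (body != body or body == ""):  # NaN or empty
            body = None
        return cls(
            animal_id=str(row["animal_id"]),
            fresh_weight_mg=float(row["fresh_weight_mg"]),
            body_weight_g=None if body is None else float(body),
            vt=float(row["vt"]),
            vv=vv,
            v=v,
            q_a=float(row["q_a"]),
            lv=float(row["lv"]),
            l_total=float(row["l_total"]),
            sv=float(row["sv"]),
            s_total=float(row["s_total"]),
            nv=nv,
            raw=raw,
        )


def build_estimate_record(
    animal_id: str,
    fresh_weight_mg: float,
    raw: dict,
    body_weight_g: float | None = None,
) -> EstimateRecord:
    """Assemble an :class:`EstimateRecord` from raw sampling tallies.

    ``raw`` must contain: ``pixels_lumen``, ``pixels_epithelium``,
    ``pixels_stroma`` (summed compartment pixels over the animal's fields),
    ``qa_count`` and ``qa_area_mm2``, ``intercepts`` and
    ``test_length_mm``, and per particle class ``count_<cls>`` with
    ``volume_mm3_<cls>`` (disector tallies).  Raises ``KeyError`` when a
    component count is missing (incomplete sampling).
    """
    vt = volume_from_weight(fresh_weight_mg)
    pixels = {
        name: float(raw[f"pixels_{name}"]) for name in ("lumen", "epithelium", "stroma")
    }
    tissue = sum(pixels.values())
    if tissue <= 0:
        raise ValueError("no tissue pixels in raw counts")
    vv = {name: px / tissue for name, px in pixels.items()}
    v = {name: f * vt for name, f in vv.items()}
    q_a = float(raw["qa_count"]) / float(raw["qa_area_mm2"])
    lv = lv_from_qa(q_a)
    l_total = total_length(lv, vt)
    sv = sv_from_intercepts(float(raw["intercepts"]), float(raw["test_length_mm"]))
    s_total = epithelial_surface(sv, vt, paper_mode=False)
    nv = {}
    for key in raw:
        if key.startswith("count_"):
            cls_name = key[len("count_") :]
            nv[cls_name] = float(raw[key]) / float(raw[f"volume_mm3_{cls_name}"])
    return EstimateRecord(
        animal_id=animal_id,
        fresh_weight_mg=fresh_weight_mg,
        body_weight_g=body_weight_g,
        vt=vt,
        vv=vv,
        v=v,
        q_a=q_a,
        lv=lv,
        l_total=l_total,
        sv=sv,
        s_total=s_total,
        nv=nv,
        raw=dict(raw),
    )


def records_to_csv(records: Sequence[EstimateRecord], path: str) -> None:
    import pandas as pd

    pd.DataFrame([r.to_row() for r in records]).to_csv(path, index=False)


def records_from_csv(path: str) -> list:
    import pandas as pd

    df = pd.read_csv(path)
    return [EstimateRecord.from_row(row) for row in df.to_dict(orient="records")]
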