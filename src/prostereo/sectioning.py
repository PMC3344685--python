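"""IUR section planes, digital sectioning and systematic field sampling.

The physical protocol this emulates cuts isotropic uniform random (IUR)
sections with an orientator and samples a fixed number of microscope fields
per section systematically with a random start.  Digitally, the same IUR law
is obtained by sampling the plane normal uniformly on the hemisphere and the
plane offset uniformly over the block's support along that normal, which is
distribution-equivalent to the two-step rotation protocol and exactly
testable.

A section plane carries a "vertical" axis (the in-plane image of the global
z axis, by fixed convention) so cycloid test grids can be oriented on it;
under IUR sampling any fixed convention yields a valid design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .phantom import LabelVolume, OUTSIDE

DEFAULT_THICKNESS = 0.005  # mm; paraffin section


class NonIntersectingPlaneError(ValueError):
    """The requested plane misses the tissue block."""


class SectionTooSmallError(RuntimeError):
    """The section does not contain enough tissue for the requested fields."""


@dataclass(frozen=True)
class SectionPlane:
    """An oriented section plane through a block.

    ``normal`` is the unit plane normal; ``offset`` the signed distance of
    the plane from the block center along the normal (mm); ``thickness`` the
    physical section thickness (mm); ``vertical_axis`` a unit vector lying
    in the plane that defines "vertical" for cycloid grids.
    """

    normal: tuple
    offset: float
    thickness: float = DEFAULT_THICKNESS
    vertical_axis: tuple | None = None

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-8:
            raise ValueError("normal must be a unit vector")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.vertical_axis is None:
            object.__setattr__(
                self, "vertical_axis", tuple(_vertical_axis_for(n))
            )
        v = np.asarray(self.vertical_axis, dtype=float)
        if abs(np.linalg.norm(v) - 1.0) > 1e-8 or abs(v @ n) > 1e-8:
            raise ValueError("vertical_axis must be a unit vector in the plane")

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.vertical_axis, dtype=float)

    @property
    def u(self) -> np.ndarray:
        """In-plane horizontal axis completing the (u, v, n) frame."""
        return np.cross(self.v, self.n)


def _vertical_axis_for(n: np.ndarray) -> np.ndarray:
    """Projection of the global z axis onto the plane (x axis if degenerate)."""
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
        v = ref - (ref @ n) * n
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm
    raise RuntimeError("unreachable: no vertical axis found")


@dataclass
class SectionField:
    """A 2D sampled field: label image plus its geometric placement.

    ``labels`` is indexed ``[row, col]`` where columns run along the plane's
    u axis and rows along its vertical axis v; ``origin`` is the in-plane
    (u, v) coordinate of the lower-left corner of pixel (0, 0).  Label codes
    are those of the phantom, with 0 marking pixels outside the block.
    ``particles`` is a dict of arrays (``cls``, ``x``, ``y``, ``depth``) for
    particles whose center lies within the captured slab.
    """

    labels: np.ndarray
    pixel_size: float
    plane: SectionPlane
    origin: tuple
    particles: dict | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.particles is None:
            self.particles = {
                "cls": np.array([], dtype=object),
                "x": np.array([]),
                "y": np.array([]),
                "depth": np.array([]),
            }

    @property
    def in_block(self) -> np.ndarray:
        return self.labels != OUTSIDE

    @property
    def tissue_area(self) -> float:
        return float(np.count_nonzero(self.in_block)) * self.pixel_size**2

    def compartment_area(self, code: int) -> float:
        return float(np.count_nonzero(self.labels == code)) * self.pixel_size**2

    @property
    def extent(self) -> tuple:
        """(width, height) of the field in mm."""
        ny, nx = self.labels.shape
        return (nx * self.pixel_size, ny * self.pixel_size)


@dataclass
class DisectorStack:
    """Two parallel registered fields separated by height ``h``.

    The look-up plane sits at depth 0, the reference plane at depth ``h``
    along the plane normal; ``particles`` carries every particle with depth
    in ``[0, h]`` relative to the look-up plane, and ``excluded`` the
    indices of particles lying exactly in the look-up plane (never counted).
    """

    lookup: SectionField
    reference: SectionField
    h: float
    particles: dict

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("disector height must be positive")

    @property
    def excluded(self) -> np.ndarray:
        return np.flatnonzero(self.particles["depth"] == 0.0)


def sample_iur_plane(
    volume: LabelVolume,
    rng: np.random.Generator | int,
    thickness: float = DEFAULT_THICKNESS,
) -> SectionPlane:
    """Draw one isotropic uniform random plane through the block.

    The normal's azimuth is uniform on [0, 2pi) and the cosine of its
    colatitude uniform on [0, 1] (uniform on the upper hemisphere); the
    offset is uniform over the block's support interval along the normal.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    z = rng.uniform(0.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - z * z))
    n = np.array([s * math.cos(phi), s * math.sin(phi), z])
    support = float(np.abs(n) @ (volume.block_edges / 2.0))
    offset = rng.uniform(-support, support)
    return SectionPlane(
        normal=tuple(n), offset=offset, thickness=thickness
    )


def plane_support(volume: LabelVolume, plane: SectionPlane) -> float:
    """Half-width of the block's support interval along the plane normal."""
    return float(np.abs(plane.n) @ (volume.block_edges / 2.0))


def extract_section(
    volume: LabelVolume,
    plane: SectionPlane,
    pixel_size: float | None = None,
) -> SectionField:
    """Cut a full digital section: the plane rasterized over the block.

    Each pixel takes the label of the voxel containing its center's 3D
    position; pixels outside the block are 0.  Particles whose center lies
    within ``thickness / 2`` of the plane are projected into the field with
    their class and signed depth retained.
    """
    ps = volume.voxel_size if pixel_size is None else float(pixel_size)
    if abs(plane.offset) > plane_support(volume, plane) + 1e-9:
        raise NonIntersectingPlaneError(
            f"plane at offset {plane.offset:.4f} misses the block"
        )
    c = volume.block_center
    r_c = float(np.linalg.norm(volume.block_edges / 2.0))  # circumradius
    npix = int(math.ceil(2.0 * r_c / ps))
    coords = (np.arange(npix) + 0.5) * ps - (npix * ps) / 2.0
    u, v, n = plane.u, plane.v, plane.n
    base = c + plane.offset * n
    # points[row, col] = base + x[col] * u + y[row] * v
    pts = (
        base[None, None, :]
        + coords[None, :, None] * u[None, None, :]
        + coords[:, None, None] * v[None, None, :]
    )
    labels = volume.label_at(pts.reshape(-1, 3)).reshape(npix, npix)
    origin = (-(npix * ps) / 2.0, -(npix * ps) / 2.0)

    cls_list, xs, ys, depths = [], [], [], []
    for cls, p in volume.particles:
        w = np.asarray(p, dtype=float) - c
        t = float(w @ n) - plane.offset
        if abs(t) <= plane.thickness / 2.0:
            cls_list.append(cls)
            xs.append(float(w @ u))
            ys.append(float(w @ v))
            depths.append(t)
    particles = {
        "cls": np.array(cls_list, dtype=object),
        "x": np.array(xs),
        "y": np.array(ys),
        "depth": np.array(depths),
    }
    return SectionField(
        labels=labels, pixel_size=ps, plane=plane, origin=origin, particles=particles
    )


def _subfield(
    section: SectionField, row0: int, col0: int, height: int, width: int
) -> SectionField:
    sub = section.labels[row0 : row0 + height, col0 : col0 + width]
    ps = section.pixel_size
    ox = section.origin[0] + col0 * ps
    oy = section.origin[1] + row0 * ps
    p = section.particles
    x_rel = p["x"] - ox
    y_rel = p["y"] - oy
    keep = (
        (x_rel >= 0)
        & (x_rel < width * ps)
        & (y_rel >= 0)
        & (y_rel < height * ps)
    )
    particles = {
        "cls": p["cls"][keep],
        "x": p["x"][keep],
        "y": p["y"][keep],
        "depth": p["depth"][keep],
    }
    return SectionField(
        labels=sub,
        pixel_size=ps,
        plane=section.plane,
        origin=(ox, oy),
        particles=particles,
    )


def tile_fields(section: SectionField, field_edge: float, start: tuple[int, int] = (0, 0)):
    """Full tiling of a section into contiguous square fields.

    ``start`` shifts the grid origin by whole pixels (the systematic random
    start).  Fields at the boundary are clipped to the section; together the
    tiles cover every pixel exactly once.
    """
    k = max(1, int(round(field_edge / section.pixel_size)))
    ny, nx = section.labels.shape
    r0, c0 = start[0] % k, start[1] % k
    rows = list(range(r0 - k if r0 else 0, ny, k))
    cols = list(range(c0 - k if c0 else 0, nx, k))
    out = []
    for r in rows:
        for c in cols:
            rr, cc = max(r, 0), max(c, 0)
            height = min(r + k, ny) - rr
            width = min(c + k, nx) - cc
            if height <= 0 or width <= 0:
                continue
            out.append(_subfield(section, rr, cc, height, width))
    return out


def systematic_fields(
    section: SectionField,
    n_fields: int = 22,
    field_edge: float = 0.25,
    rng: np.random.Generator | int = 0,
    min_tissue_fraction: float = 0.0,
    allow_fewer: bool = False,
    return_info: bool = False,
):
    """Systematically sample tissue-containing square fields from a section.

    A grid of contiguous ``field_edge``-sized fields with a single uniform
    random start covers the section; fields with no tissue (or less than
    ``min_tissue_fraction`` of their area in tissue) are skipped, and the
    surviving candidates are subsampled systematically (again with a random
    start) down to exactly ``n_fields``.  Raises
    :class:`SectionTooSmallError` if the section cannot yield enough fields,
    unless ``allow_fewer`` is set, in which case all candidates are
    returned.

    With ``return_info`` the function returns ``(fields, info)`` where
    ``info["weight"]`` is the inverse sampling fraction
    (candidates / sampled).  When a fixed number of fields is drawn from
    sections offering different numbers of candidate fields, pooled
    ratio-of-sums estimators must scale each section's sums by this weight,
    otherwise sections with few candidates are over-represented.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = max(1, int(round(field_edge / section.pixel_size)))
    start = (int(rng.integers(0, k)), int(rng.integers(0, k)))
    full_area = k * k
    candidates = []
    for f in tile_fields(section, field_edge, start):
        frac = np.count_nonzero(f.in_block) / full_area
        if frac > 0 and frac >= min_tissue_fraction:
            candidates.append(f)
    def _pack(sampled, n_candidates):
        if not return_info:
            return sampled
        weight = n_candidates / len(sampled) if sampled else 1.0
        return sampled, {
            "n_candidates": n_candidates,
            "n_sampled": len(sampled),
            "weight": weight,
        }

    if len(candidates) < n_fields:
        if allow_fewer:
            return _pack(candidates, len(candidates))
        raise SectionTooSmallError(
            f"section yields only {len(candidates)} tissue fields, "
            f"{n_fields} requested"
        )
    if len(candidates) == n_fields:
        return _pack(candidates, len(candidates))
    step = len(candidates) / n_fields
    u0 = rng.uniform(0.0, step)
    idx = [int(u0 + i * step) for i in range(n_fields)]
    return _pack([candidates[i] for i in idx], len(candidates))


def make_disector(
    volume: LabelVolume,
    plane: SectionPlane,
    h: float,
    pixel_size: float | None = None,
) -> DisectorStack:
    """Build an optical-disector stack of height ``h`` on top of ``plane``.

    The given plane is the look-up plane (depth 0); the reference plane lies
    at depth ``h`` along the normal.  Both fields share orientation and
    lateral origin.  Every particle with depth in ``[0, h]`` is retained
    with its class and depth; the disector counting rule itself lives in
    :func:`prostereo.estimators.nv_optical_disector`.
    """
    if h <= 0:
        raise ValueError("disector height h must be positive")
    support = plane_support(volume, plane)
    if h > 2 * support:
        raise ValueError("disector height exceeds the block extent")
    ref_plane = replace(plane, offset=plane.offset + h)
    if abs(plane.offset) > support + 1e-9 or abs(ref_plane.offset) > support + 1e-9:
        raise NonIntersectingPlaneError("disector planes must intersect the block")
    lookup = extract_section(volume, plane, pixel_size)
    reference = extract_section(volume, ref_plane, pixel_size)
    c = volume.block_center
    u, v, n = plane.u, plane.v, plane.n
    cls_list, xs, ys, depths = [], [], [], []
    for cls, p in volume.particles:
        w = np.asarray(p, dtype=float) - c
        t = float(w @ n) - plane.offset
        if abs(t) < 1e-12:
            t = 0.0  # exactly in focus at the look-up plane
        if 0.0 <= t <= h:
            cls_list.append(cls)
            xs.append(float(w @ u))
            ys.append(float(w @ v))
            depths.append(t)
    particles = {
        "cls": np.array(cls_list, dtype=object),
        "x": np.array(xs),
        "y": np.array(ys),
        "depth": np.array(depths),
    }
    return DisectorStack(lookup=lookup, reference=reference, h=h, particles=particles)


# ---------------------------------------------------------------------------
# field image IO: single-channel TIFF/PNG plus a JSON sidecar


def save_field(field: SectionField, path: str) -> None:
    """Write a field's label image (TIFF or PNG) with a JSON sidecar."""
    import tifffile

    arr = field.labels.astype(np.uint8)
    if str(path).lower().endswith(".png"):
        from PIL import Image

        Image.fromarray(arr, mode="L").save(path)
    else:
        tifffile.imwrite(path, arr)
    meta = {
        "pixel_size_mm": field.pixel_size,
        "origin_mm": list(field.origin),
        "plane": {
            "normal": list(field.plane.normal),
            "offset_mm": field.plane.offset,
            "thickness_mm": field.plane.thickness,
            "vertical_axis": list(field.plane.vertical_axis),
        },
        "label_legend": {"0": "outside", "1": "lumen", "2": "epithelium", "3": "stroma"},
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_field(path: str) -> SectionField:
    """Read a field image and its JSON sidecar written by :func:`save_field`."""
    if str(path).lower().endswith(".png"):
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=np.uint8)
    else:
        import tifffile

        arr = tifffile.imread(path).astype(np.uint8)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    plane = SectionPlane(
        normal=tuple(meta["plane"]["normal"]),
        offset=meta["plane"]["offset_mm"],
        thickness=meta["plane"]["thickness_mm"],
        vertical_axis=tuple(meta["plane"]["vertical_axis"]),
    )
    return SectionField(
        labels=arr,
        pixel_size=meta["pixel_size_mm"],
        plane=plane,
        origin=tuple(meta["origin_mm"]),
    )
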