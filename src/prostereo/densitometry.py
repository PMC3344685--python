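"""Integrated optical density (IOD) of stained nuclei.

Semi-quantitative immunostaining readout: a fixed-size rectangle is cropped
from the center of each sampled nucleus, every pixel's transmitted intensity
is converted to optical density by the Beer-Lambert relation
``OD = log10(I_ref / I)`` against a white reference, and the IOD of the
nucleus is the sum of OD over the rectangle.  Stronger staining transmits
less light and yields a higher IOD; halving transmittance adds log10(2) to
every pixel.

The synthetic renderer draws elliptical nuclei with Gaussian-profile
absorbance on a bright background; images are single-channel (no color
deconvolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Optical density ceiling; bounds the log blow-up on near-zero pixels.
OD_CEILING = 3.0


@dataclass
class NucleusROI:
    """Fixed-size rectangular crop centred on one nucleus."""

    pixels: np.ndarray  # transmitted intensities, [0, I_max]
    group: str
    center: tuple | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class IODResult:
    """Per-group IOD summary."""

    group: str
    iods: np.ndarray
    mean: float
    sd: float
    n: int


def od_map(
    intensities: np.ndarray,
    incident_reference: float,
    ceiling: float = OD_CEILING,
) -> np.ndarray:
    """Per-pixel optical density OD = log10(I_ref / max(I, 1)), clipped.

    ``incident_reference`` is the white-background calibration intensity;
    intensities are floored at 1 count before the log so dead pixels map to
    the ceiling rather than infinity.
    """
    if incident_reference <= 0:
        raise ValueError("incident reference intensity must be positive")
    arr = np.maximum(np.asarray(intensities, dtype=float), 1.0)
    od = np.log10(incident_reference / arr)
    return np.clip(od, 0.0, ceiling)


def integrated_od(roi: NucleusROI, incident_reference: float) -> float:
    """IOD of one nucleus: sum of optical density over the rectangle."""
    return float(od_map(roi.pixels, incident_reference).sum())


def render_nuclei_image(
    n_nuclei: int,
    shape: tuple[int, int],
    rng: np.random.Generator | int,
    peak_od: float = 0.8,
    od_sd: float = 0.08,
    transmittance_factor: float = 1.0,
    sigma_px: float = 6.0,
    background: float = 230.0,
    margin: int = 16,
) -> tuple[np.ndarray, list]:
    """Render a synthetic stained-nuclei field.

    Nuclei are Gaussian-profile absorbers of peak optical density
    ``peak_od`` (jittered by ``od_sd``) on a bright background of intensity
    ``background``.  ``transmittance_factor`` m scales the light each
    nucleus transmits: every stained pixel's OD is reduced by log10(m)
    (floored at 0), so m = 2 transmits twice as much light.  Returns the
    image and the list of nucleus centers ``(row, col)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = shape
    od = np.zeros((h, w), dtype=float)
    centers = []
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for _ in range(n_nuclei):
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        amp = max(0.05, rng.normal(peak_od, od_sd))
        sx = sigma_px * rng.uniform(0.8, 1.2)
        sy = sigma_px * rng.uniform(0.8, 1.2)
        od += amp * np.exp(
            -((rows - r) ** 2 / (2 * sy**2) + (cols - c) ** 2 / (2 * sx**2))
        )
        centers.append((r, c))
    od = np.maximum(0.0, od - math.log10(transmittance_factor))
    image = background * np.power(10.0, -od)
    return image, centers


def sample_nuclei(
    images: list,
    n_per_group: int = 100,
    rng: np.random.Generator | int = 0,
    roi_shape: tuple[int, int] = (21, 21),
    group: str = "",
) -> list:
    """Randomly select nuclei and crop fixed rectangles around them.

    ``images`` is a list of ``(image, centers)`` pairs (one per histological
    section); the selection is uniform without replacement over all detected
    nuclei of the group, seeded for reproducibility.  Raises ``ValueError``
    when fewer nuclei are available than requested.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pool = []
    for image, centers in images:
        for (r, c) in centers:
            pool.append((image, r, c))
    if len(pool) < n_per_group:
        raise ValueError(
            f"only {len(pool)} nuclei available, {n_per_group} requested"
        )
    idx = rng.choice(len(pool), size=n_per_group, replace=False)
    hh, ww = roi_shape
    rois = []
    for i in idx:
        image, r, c = pool[int(i)]
        r0 = int(round(r)) - hh // 2
        c0 = int(round(c)) - ww // 2
        r0 = max(0, min(r0, image.shape[0] - hh))
        c0 = max(0, min(c0, image.shape[1] - ww))
        rois.append(
            NucleusROI(
                pixels=image[r0 : r0 + hh, c0 : c0 + ww].copy(),
                group=group,
                center=(r, c),
            )
        )
    return rois


def group_iod(
    rois: list, incident_reference: float, group: str | None = None
) -> IODResult:
    """Summarise IOD over a set of ROIs (mean, sample SD, n)."""
    vals = np.array([integrated_od(r, incident_reference) for r in rois])
    if group is None:
        group = rois[0].group if rois else ""
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return IODResult(
        group=group, iods=vals, mean=float(vals.mean()), sd=sd, n=len(vals)
    )
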