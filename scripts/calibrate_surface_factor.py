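#!/usr/bin/env python
"""Measure the voxel-face surface calibration factor on digital balls.

Counting exposed voxel faces measures the surface integral of
|nx| + |ny| + |nz|, which for a sphere (or any isotropically oriented
surface) equals 3/2 of the true area; the package therefore multiplies raw
face counts by 2/3 (``prostereo.phantom.SURFACE_CALIBRATION``).  This
script reproduces that number empirically at several resolutions::

    python scripts/calibrate_surface_factor.py
"""

import math

import numpy as np

from prostereo.phantom import LUMEN, STROMA, EPITHELIUM, voxel_face_surface


def ball_factor(radius_voxels: float) -> float:
    n = int(2 * radius_voxels + 8)
    c = n / 2.0
    idx = np.arange(n) + 0.5
    X, Y, Z = np.meshgrid(idx - c, idx - c, idx - c, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    labels = np.where(r2 <= radius_voxels**2, LUMEN, EPITHELIUM).astype(np.uint8)
    raw = voxel_face_surface(labels, 1.0)
    true = 4.0 * math.pi * radius_voxels**2
    return true / raw


if __name__ == "__main__":
    for r in (10, 25, 50, 100):
        f = ball_factor(r)
        print(f"radius {r:4d} voxels: calibration factor {f:.4f} (2/3 = {2/3:.4f})")
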