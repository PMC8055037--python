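#!/usr/bin/env python
"""Regenerate the bundled Forel-Ule synthetic reconstruction fixture.

The physical Forel-Ule standard's measured tristimulus values (from
transmission spectroscopy of the original pigment solutions) are published
elsewhere and are not redistributed with this package. The bundled table is
a one-off synthetic reconstruction built from the scale's documented
structure:

* hue angles around the equal-energy (E) white point sweeping from the
  indigo-blue region (FU 1, ~230 deg, measured counterclockwise from the
  positive chromaticity x axis) through green to cola brown (FU 21, ~23 deg),
  with the blue->green transition spread over FU 5-9;
* a saturation (chromaticity distance from white) profile that is high at
  the blue end, dips at the blue-green transition, and recovers through
  green towards brown;
* a lightness profile that is low at both extremes and peaks at the mid
  greens.

All colours lie inside the sRGB gamut after adaptation to D65, matching the
documented gamut of the scale. Running this script rewrites
``src/cvdscale/data/forel_ule_synthetic.csv``; the pinned checksum in
``cvdscale.scale`` must be updated whenever the construction changes.
"""

from pathlib import Path

import numpy as np

from cvdscale.core import chromatic_adapt, chromaticity_to_xyz, xyz_to_linear_srgb

HUE_DEG = np.array([
    229.9, 224.7, 217.0, 203.1, 178.9, 147.6, 118.3, 99.8, 88.4, 78.1, 71.2,
    65.1, 59.2, 54.0, 49.0, 44.0, 39.6, 34.9, 30.9, 26.7, 22.9,
])
SATURATION = np.array([
    0.217, 0.186, 0.150, 0.115, 0.0875, 0.089, 0.115, 0.141, 0.156, 0.176,
    0.169, 0.163, 0.159, 0.162, 0.167, 0.172, 0.178, 0.184, 0.188, 0.192, 0.195,
])
LIGHTNESS = np.array([
    43, 47, 52, 57, 62, 66, 70, 73, 76, 78, 79, 79, 78, 76, 74, 71, 67, 62,
    57, 51, 45,
], dtype=float)

HEADER = """\
# Forel-Ule 21-step water-colour scale -- SYNTHETIC RECONSTRUCTION
# ---------------------------------------------------------------
# These are NOT the measured tristimulus values of the physical Forel-Ule
# standard (which are published from transmission spectroscopy of the
# original pigment solutions and are not reproduced here). This table is a
# one-off synthetic reconstruction built from the scale's documented
# structure: a hue-angle progression around the equal-energy (E) white point
# from indigo blue (FU 1, ~230 deg) through green (FU 11) to cola brown
# (FU 21, ~23 deg); a saturation profile that dips at the blue-green
# transition; and a lightness profile peaking at the mid greens.
# Illuminant: E (equal energy), white point Y = 1; XYZ on the Y-in-[0,1]
# scale. Regenerate with scripts/build_fu_fixture.py; see docs/methods.md.
# Columns: label, X, Y, Z.
"""


def build() -> np.ndarray:
    white = np.array([1 / 3, 1 / 3])
    angle = np.radians(HUE_DEG)
    xy = white + SATURATION[:, None] * np.stack([np.cos(angle), np.sin(angle)], -1)
    luminance = ((LIGHTNESS + 16) / 116) ** 3
    xyz = chromaticity_to_xyz(xy, luminance)
    rgb = xyz_to_linear_srgb(chromatic_adapt(xyz, "E", "D65"))
    if not np.all((rgb >= -1e-9) & (rgb <= 1 + 1e-9)):
        raise RuntimeError("reconstruction left the sRGB gamut")
    return xyz


def main() -> None:
    xyz = build()
    out = Path(__file__).resolve().parent.parent / "src/cvdscale/data/forel_ule_synthetic.csv"
    lines = [HEADER, "label,X,Y,Z\n"]
    for i, (x, y, z) in enumerate(xyz):
        lines.append(f"{i + 1},{x:.6f},{y:.6f},{z:.6f}\n")
    out.write_text("".join(lines))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
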