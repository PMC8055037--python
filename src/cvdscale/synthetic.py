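"""Synthetic colour scales with controlled structure.

These generators produce small scales whose geometry is known by
construction, so every pipeline stage (simulation, Lab conversion,
confusion matrices, sweeps) can be exercised and checked without the bundled
water-colour fixture:

* ``gen_random_scale`` — colours sampled uniformly in chromaticity inside the
  sRGB triangle at a fixed luminance; an unstructured baseline.
* ``gen_metamer_pair`` — two colours that agree in the two cones unaffected
  by a chosen deficiency and differ only in the deficient cone. At full
  severity (k = 0) the simulation must map them to the same colour.
* ``gen_hue_ramp`` — a deterministic hue sweep from blue towards brown at
  smoothly varying lightness, mimicking the structure of a water-colour
  scale; adjacent colours are closest by construction.

All generators are pure functions of their arguments (seeded) and their
output survives a CSV round trip through :mod:`cvdscale.scale` unchanged.
"""

from __future__ import annotations

import numpy as np

from .core import (
    chromaticity_to_xyz,
    lms_to_xyz,
    xyz_to_linear_srgb,
    xyz_to_lms,
)
from .cvd import _check_deficiency  # shared validation of deficiency names
from .scale import ColourScale

__all__ = [
    "gen_random_scale",
    "gen_metamer_pair",
    "gen_hue_ramp",
    "gen_constant_scale",
]

# sRGB primary chromaticities: the triangle random colours are drawn from.
_TRIANGLE = np.array([[0.6400, 0.3300], [0.3000, 0.6000], [0.1500, 0.0600]])

_E_WHITE_XY = np.array([1.0 / 3.0, 1.0 / 3.0])


def _in_srgb_gamut(xyz) -> np.ndarray:
    rgb = xyz_to_linear_srgb(xyz)
    return np.all((rgb >= -1e-9) & (rgb <= 1 + 1e-9), axis=-1)


def gen_random_scale(
    count: int,
    seed: int,
    luminance_y: float = 0.4,
    name: str = "random",
) -> ColourScale:
    """Random in-gamut colours at fixed luminance, illuminant E.

    Chromaticities are drawn uniformly over the sRGB triangle (slightly
    shrunk towards its centroid so the fixed luminance stays displayable),
    then lifted to XYZ at ``luminance_y``. Deterministic under ``seed``.
    """
    if count < 2:
        raise ValueError("count must be >= 2")
    rng = np.random.default_rng(seed)
    # Uniform sampling over a triangle via the square-root trick.
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    a, b, c = _TRIANGLE
    xy = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c
    centroid = _TRIANGLE.mean(axis=0)
    xy = centroid + 0.7 * (xy - centroid)
    xyz = chromaticity_to_xyz(xy, luminance_y)
    labels = tuple(str(i + 1) for i in range(count))
    return ColourScale(name=name, labels=labels, xyz=xyz, illuminant="E")


def gen_constant_scale(count: int, luminance_y: float = 0.4) -> ColourScale:
    """``count`` copies of the same grey; every pairwise difference is zero."""
    if count < 2:
        raise ValueError("count must be >= 2")
    xyz = np.tile([luminance_y, luminance_y, luminance_y], (count, 1))
    labels = tuple(str(i + 1) for i in range(count))
    return ColourScale(name="constant", labels=labels, xyz=xyz, illuminant="E")


def gen_metamer_pair(
    deficiency: str,
    seed: int,
    max_attempts: int = 100,
) -> ColourScale:
    """Two colours separated only along the deficient cone axis.

    The pair agrees exactly in the two unaffected cone responses, so a
    complete deficiency (k = 0) maps both to the same colour: they are
    dichromat metamers. The perturbation is shrunk geometrically until both
    members lie inside the sRGB gamut; construction fails (``RuntimeError``)
    only after ``max_attempts`` shrink steps.
    """
    d = _check_deficiency(deficiency)
    axis = {"protan": 0, "deutan": 1, "tritan": 2}[d]
    rng = np.random.default_rng(seed)
    # Start near mid grey (ample gamut headroom in every direction), with a
    # small random offset so different seeds give different pairs.
    base_lms = xyz_to_lms(np.full(3, 0.35)) + rng.uniform(-0.04, 0.04, size=3)
    delta = 0.12
    for _ in range(max_attempts):
        partner_lms = base_lms.copy()
        partner_lms[axis] += delta
        pair = lms_to_xyz(np.stack([base_lms, partner_lms]))
        if np.all(_in_srgb_gamut(pair)) and np.all(pair >= 0):
            return ColourScale(
                name=f"metamer-{d}",
                labels=("a", "b"),
                xyz=pair,
                illuminant="E",
            )
        delta *= 0.7
    raise RuntimeError(f"could not construct an in-gamut {d} metamer pair")


def gen_hue_ramp(count: int, name: str = "hue-ramp") -> ColourScale:
    """Deterministic blue-to-brown hue ramp, illuminant E.

    Chromaticities move on an arc around the equal-energy white from the
    blue region (hue angle ~230 deg, measured counterclockwise from the
    positive x axis at the white point) through green and yellow down to
    orange-brown (~25 deg), at moderate saturation; lightness rises from the
    blue end to the middle and falls again towards the brown end. Adjacent
    colours are the closest pairs by construction.
    """
    if count < 2:
        raise ValueError("count must be >= 2")
    t = np.linspace(0.0, 1.0, count)
    angle = np.radians(230.0 - 205.0 * t)
    sat = 0.17 - 0.05 * np.sin(np.pi * t)
    xy = _E_WHITE_XY + sat[:, None] * np.stack([np.cos(angle), np.sin(angle)], axis=-1)
    lightness = 45.0 + 30.0 * np.sin(np.pi * t)
    y_lum = ((lightness + 16.0) / 116.0) ** 3
    xyz = chromaticity_to_xyz(xy, y_lum)
    labels = tuple(str(i + 1) for i in range(count))
    return ColourScale(name=name, labels=labels, xyz=xyz, illuminant="E")
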