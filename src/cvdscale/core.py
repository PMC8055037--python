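"""Colour-space primitives shared by the whole pipeline.

All operations act on CIE XYZ tristimulus vectors stored as numpy arrays of
shape ``(..., 3)``; single colours are plain length-3 arrays. Linear-light
spaces (XYZ, LMS, linear sRGB) are converted by fixed 3x3 matrices, the
perceptual space is CIE 1976 L*a*b* relative to an illuminant white point.

Conventions
-----------
* White points are stored normalised to Y = 1. The L*a*b* conversion works on
  ratios to the white point, so any common scaling of colours and white
  cancels; colours are expected on the same Y-in-[0, 1] scale.
* The XYZ -> LMS transform is the Hunt-Pointer-Estevez matrix (cone
  fundamentals normalised to the equal-energy white), the space in which cone
  deficiencies are modelled.
* Chromatic adaptation uses the Bradford linear method; the adaptation matrix
  is built at import time from the two white points rather than transcribed
  from tables, and is regression-tested against published matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Illuminant",
    "ILLUMINANTS",
    "HUNT_POINTER_ESTEVEZ",
    "BRADFORD",
    "get_illuminant",
    "xyz_to_lms",
    "lms_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "xyz_to_chromaticity",
    "chromaticity_to_xyz",
    "bradford_matrix",
    "chromatic_adapt",
    "xyz_to_linear_srgb",
    "linear_srgb_to_xyz",
    "xyz_to_srgb",
    "srgb_hex",
]


# Hunt-Pointer-Estevez cone-fundamental matrix (equal-energy normalisation):
# rows give the L, M, S cone excitations of an XYZ tristimulus vector.
HUNT_POINTER_ESTEVEZ = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_HPE_INV = np.linalg.inv(HUNT_POINTER_ESTEVEZ)

# Bradford cone-response matrix used for chromatic adaptation.
BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_BRADFORD_INV = np.linalg.inv(BRADFORD)


@dataclass(frozen=True)
class Illuminant:
    """A standard illuminant: a name and its white point (Y = 1)."""

    name: str
    white_xyz: tuple[float, float, float]

    def white(self) -> np.ndarray:
        return np.array(self.white_xyz, dtype=float)


# CIE 1931 2-degree observer white points (ASTM E308 / Lindbloom), Y = 1.
ILLUMINANTS: dict[str, Illuminant] = {
    "E": Illuminant("E", (1.0, 1.0, 1.0)),
    "D55": Illuminant("D55", (0.95682, 1.0, 0.92149)),
    "D65": Illuminant("D65", (0.95047, 1.0, 1.08883)),
    "D75": Illuminant("D75", (0.94972, 1.0, 1.22638)),
}


def get_illuminant(illuminant: str | Illuminant) -> Illuminant:
    """Resolve an illuminant name to its definition.

    Raises ``ValueError`` for illuminants outside the supported set
    {E, D55, D65, D75}.
    """
    if isinstance(illuminant, Illuminant):
        return illuminant
    try:
        return ILLUMINANTS[illuminant.upper()]
    except KeyError:
        raise ValueError(
            f"unsupported illuminant {illuminant!r}; "
            f"supported: {sorted(ILLUMINANTS)}"
        ) from None


def _as_colours(values, name: str = "colour") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"{name} must have 3 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite {name} values")
    return arr


def xyz_to_lms(xyz) -> np.ndarray:
    """Convert XYZ tristimulus values to LMS cone excitations."""
    return _as_colours(xyz, "XYZ") @ HUNT_POINTER_ESTEVEZ.T


def lms_to_xyz(lms) -> np.ndarray:
    """Convert LMS cone excitations back to XYZ (exact matrix inverse)."""
    return _as_colours(lms, "LMS") @ _HPE_INV.T


def xyz_to_chromaticity(xyz) -> np.ndarray:
    """Project XYZ onto the (x, y) chromaticity plane.

    Undefined (raises ``ValueError``) where X + Y + Z = 0.
    """
    arr = _as_colours(xyz, "XYZ")
    total = arr.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("chromaticity undefined for X + Y + Z = 0")
    return arr[..., :2] / total[..., None]


def chromaticity_to_xyz(xy, luminance_y=1.0) -> np.ndarray:
    """Lift (x, y) chromaticities to XYZ at the given luminance Y."""
    xy = np.asarray(xy, dtype=float)
    y_lum = np.asarray(luminance_y, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    if np.any(y <= 0):
        raise ValueError("chromaticity y must be positive to recover XYZ")
    x, y, y_lum = np.broadcast_arrays(x, y, y_lum)
    return np.stack([x / y * y_lum, y_lum, (1 - x - y) / y * y_lum], axis=-1)


# --- CIE 1976 L*a*b* ---------------------------------------------------------

_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    cube = _LAB_DELTA**3
    return np.where(t > cube, np.cbrt(t), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _LAB_DELTA, t**3, 3 * _LAB_DELTA**2 * (t - 4.0 / 29.0))


def xyz_to_lab(xyz, white: str | Illuminant = "E") -> np.ndarray:
    """Convert XYZ to CIE 1976 L*a*b* relative to the given reference white.

    The white point must match the illuminant the colours are currently
    expressed in; for the Forel-Ule analysis that is illuminant E unless the
    scale has been chromatically adapted.
    """
    wp = get_illuminant(white).white()
    if np.any(wp <= 0):
        raise ValueError("reference white must have strictly positive XYZ")
    ratios = _lab_f(_as_colours(xyz, "XYZ") / wp)
    fx, fy, fz = ratios[..., 0], ratios[..., 1], ratios[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_xyz(lab, white: str | Illuminant = "E") -> np.ndarray:
    """Inverse of :func:`xyz_to_lab`."""
    wp = get_illuminant(white).white()
    arr = _as_colours(lab, "Lab")
    fy = (arr[..., 0] + 16.0) / 116.0
    fx = fy + arr[..., 1] / 500.0
    fz = fy - arr[..., 2] / 200.0
    return np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * wp


# --- Bradford chromatic adaptation -------------------------------------------


def bradford_matrix(source: str | Illuminant, target: str | Illuminant) -> np.ndarray:
    """Linear XYZ->XYZ Bradford adaptation matrix between two illuminants.

    Built from the two white points: M = B^-1 diag(rho_t/rho_s) B, where rho
    are the Bradford cone responses of the whites. Maps the source white to
    the target white exactly.
    """
    src = get_illuminant(source).white()
    dst = get_illuminant(target).white()
    rho_s = BRADFORD @ src
    rho_t = BRADFORD @ dst
    return _BRADFORD_INV @ np.diag(rho_t / rho_s) @ BRADFORD


def chromatic_adapt(xyz, source: str | Illuminant, target: str | Illuminant) -> np.ndarray:
    """Re-express XYZ colours under a different illuminant (Bradford)."""
    src = get_illuminant(source)
    dst = get_illuminant(target)
    arr = _as_colours(xyz, "XYZ")
    if src.name == dst.name:
        return arr.copy()
    return arr @ bradford_matrix(src, dst).T


# --- sRGB (display swatches only) --------------------------------------------

# sRGB primaries are defined by chromaticity; the XYZ matrix is derived from
# them with the D65 white, the canonical construction.
_SRGB_CHROMA = np.array([[0.6400, 0.3300], [0.3000, 0.6000], [0.1500, 0.0600]])
_D65_WHITE = np.array(ILLUMINANTS["D65"].white_xyz)


def _srgb_matrices() -> tuple[np.ndarray, np.ndarray]:
    prim = np.stack(
        [chromaticity_to_xyz(c, 1.0) for c in _SRGB_CHROMA]
    ).T  # columns = r, g, b at Y=1
    scale = np.linalg.solve(prim, _D65_WHITE)
    rgb_to_xyz = prim * scale
    return rgb_to_xyz, np.linalg.inv(rgb_to_xyz)


_RGB_TO_XYZ, _XYZ_TO_RGB = _srgb_matrices()


def linear_srgb_to_xyz(rgb) -> np.ndarray:
    """Linear (not gamma-encoded) sRGB to XYZ under D65."""
    return _as_colours(rgb, "RGB") @ _RGB_TO_XYZ.T


def xyz_to_linear_srgb(xyz) -> np.ndarray:
    """XYZ (D65-adapted) to linear sRGB, no clipping."""
    return _as_colours(xyz, "XYZ") @ _XYZ_TO_RGB.T


def _srgb_gamma(linear: np.ndarray) -> np.ndarray:
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1.0 / 2.4) - 0.055,
    )


def xyz_to_srgb(xyz) -> np.ndarray:
    """XYZ (D65-adapted) to display sRGB in [0, 1].

    Out-of-gamut values are clipped per channel before gamma encoding. This
    is for swatch rendering only and is never used in the discriminability
    analysis.
    """
    linear = np.clip(xyz_to_linear_srgb(xyz), 0.0, 1.0)
    return _srgb_gamma(linear)


def srgb_hex(xyz) -> np.ndarray:
    """XYZ (D65-adapted) to '#rrggbb' hex strings for swatch export."""
    rgb8 = np.rint(xyz_to_srgb(xyz) * 255).astype(int)
    flat = rgb8.reshape(-1, 3)
    out = np.array([f"#{r:02x}{g:02x}{b:02x}" for r, g, b in flat])
    return out.reshape(rgb8.shape[:-1])
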