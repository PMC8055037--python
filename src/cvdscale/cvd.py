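"""Cone-deficiency transfer matrices and colour-blindness simulation.

Colour vision deficiency is modelled in LMS cone space by a 3x3 transfer
matrix ``T_k`` that leaves the two unaffected cone responses untouched and
replaces the deficient cone's response with a mixture controlled by the
relative cone contribution ``k``: ``k = 1`` is regular trichromatic vision,
``k = 0`` is dichromacy (the cone contributes nothing of its own), and
intermediate values represent anomalous trichromacy.

The off-diagonal mixture weights ``q1, q2`` of the deficient row are fixed by
two observed invariances of dichromatic vision: white is perceived unchanged,
and so is a complementary primary — blue for protan (L) and deutan (M)
deficiencies, red for tritan (S). With white proportional to (1, 1, 1) in the
equal-energy-normalised LMS space, these two eigenvector conditions give the
closed forms::

    protan:  q2 = (1 - k) (M_b - L_b) / (M_b - S_b)
    deutan:  q2 = (1 - k) (L_b - M_b) / (L_b - S_b)
    tritan:  q2 = (1 - k) (L_r - S_r) / (L_r - M_r)
    q1 = 1 - k - q2                    (deficient-row sum is 1)

where ``(L_b, M_b, S_b)`` and ``(L_r, M_r, S_r)`` are the LMS coordinates of
the sRGB blue and red primaries, the conventional choice. The conditions are
invariant to a positive rescaling of either primary.

Monochromacy (loss of more than one cone class) is outside this model and is
rejected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import linear_srgb_to_xyz, lms_to_xyz, xyz_to_lms

__all__ = [
    "DEFICIENCIES",
    "ReferencePrimaries",
    "TransferMatrix",
    "reference_primaries",
    "solve_q",
    "build_transfer_matrix",
    "simulate_deficiency",
    "k_grid",
]

#: The three dichromacy/anomalous-trichromacy families, by deficient cone.
DEFICIENCIES = ("protan", "deutan", "tritan")

# Deficient row index per family: protan = L row, deutan = M row, tritan = S.
_ROW = {"protan": 0, "deutan": 1, "tritan": 2}


def _check_deficiency(deficiency: str) -> str:
    d = str(deficiency).lower()
    if d in ("monochromacy", "monochromat", "achromatopsia"):
        raise ValueError(
            "monochromacy (loss of multiple cone classes) is outside the "
            "single-cone transfer-matrix model and is not supported"
        )
    if d not in _ROW:
        raise ValueError(f"unknown deficiency {deficiency!r}; expected one of {DEFICIENCIES}")
    return d


def _check_k(severity_k: float) -> float:
    k = float(severity_k)
    if not np.isfinite(k) or not 0.0 <= k <= 1.0:
        raise ValueError(f"severity k must lie in [0, 1], got {severity_k!r}")
    return k


@dataclass(frozen=True)
class ReferencePrimaries:
    """LMS coordinates of the reference colours whose perception is preserved."""

    blue_lms: np.ndarray
    red_lms: np.ndarray
    white_lms: np.ndarray

    def __post_init__(self):
        for name in ("blue_lms", "red_lms", "white_lms"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


def reference_primaries() -> ReferencePrimaries:
    """sRGB blue and red primaries (linear, D65) expressed in LMS.

    The absolute normalisation is irrelevant: the eigenvector conditions that
    consume these vectors are scale-invariant.
    """
    blue = xyz_to_lms(linear_srgb_to_xyz([0.0, 0.0, 1.0]))
    red = xyz_to_lms(linear_srgb_to_xyz([1.0, 0.0, 0.0]))
    white = np.ones(3)
    return ReferencePrimaries(blue_lms=blue, red_lms=red, white_lms=white)


_DEFAULT_PRIMARIES = reference_primaries()


def solve_q(
    deficiency: str,
    severity_k: float,
    primaries: ReferencePrimaries | None = None,
) -> tuple[float, float]:
    """Mixture weights (q1, q2) of the deficient row of ``T_k``.

    Closed-form solution of the white + complementary-primary eigenvector
    system; see the module docstring. Raises ``ValueError`` for degenerate
    primaries (zero denominator).
    """
    d = _check_deficiency(deficiency)
    k = _check_k(severity_k)
    p = primaries if primaries is not None else _DEFAULT_PRIMARIES
    lb, mb, sb = p.blue_lms
    lr, mr, sr = p.red_lms
    if d == "protan":
        denom = mb - sb
        numer = mb - lb
    elif d == "deutan":
        denom = lb - sb
        numer = lb - mb
    else:  # tritan
        denom = lr - mr
        numer = lr - sr
    if denom == 0:
        raise ValueError(f"degenerate reference primaries for {d}: zero denominator")
    q2 = (1.0 - k) * numer / denom
    q1 = 1.0 - k - q2
    return q1, q2


@dataclass(frozen=True)
class TransferMatrix:
    """A cone-deficiency transfer matrix ``T_k`` in LMS space."""

    deficiency: str
    severity_k: float
    q1: float
    q2: float
    matrix: np.ndarray = field(repr=False)

    def __matmul__(self, other):
        return self.matrix @ other


def build_transfer_matrix(
    deficiency: str,
    severity_k: float,
    primaries: ReferencePrimaries | None = None,
) -> TransferMatrix:
    """Construct ``T_k``: identity with the deficient row replaced.

    Row layouts (deficient-cone coefficient ``k`` on the diagonal)::

        protan: (k,  q1, q2)    in row L
        deutan: (q1, k,  q2)    in row M
        tritan: (q1, q2, k )    in row S
    """
    d = _check_deficiency(deficiency)
    k = _check_k(severity_k)
    q1, q2 = solve_q(d, k, primaries)
    mat = np.eye(3)
    row = _ROW[d]
    if d == "protan":
        mat[row] = [k, q1, q2]
    elif d == "deutan":
        mat[row] = [q1, k, q2]
    else:
        mat[row] = [q1, q2, k]
    return TransferMatrix(deficiency=d, severity_k=k, q1=q1, q2=q2, matrix=mat)


def simulate_deficiency(
    xyz,
    deficiency: str,
    severity_k: float,
    primaries: ReferencePrimaries | None = None,
) -> np.ndarray:
    """Simulate colour-deficient appearance of XYZ colours.

    Pipeline: XYZ -> LMS (Hunt-Pointer-Estevez) -> multiply by ``T_k`` ->
    LMS -> XYZ. Input order is preserved and the input is not modified.
    An empty colour list maps to an empty result.
    """
    arr = np.asarray(xyz, dtype=float)
    if arr.size == 0:
        return arr.reshape(arr.shape).copy()
    tk = build_transfer_matrix(deficiency, severity_k, primaries)
    return lms_to_xyz(xyz_to_lms(arr) @ tk.matrix.T)


def k_grid(step: float = 0.01) -> np.ndarray:
    """Severity grid from 1 down to 0 inclusive, stored as exact multiples.

    The default step 0.01 gives the 101-point grid used throughout the
    analysis. ``step`` must divide 1 into an integer number of intervals.
    """
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9 or n < 1:
        raise ValueError(f"step {step!r} does not divide 1 exactly")
    return np.round(np.arange(n, -1, -1) / n, 10)
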