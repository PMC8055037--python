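"""Perceptual discriminability of colour-scale pairs.

Pairwise colour differences are measured with the CIEDE2000 metric (dE00)
in CIE L*a*b* space, with all parametric weights at their reference values
kL = kC = kH = 1. One just-noticeable difference (JND) is taken as
dE00 = 2.3, the smallest difference an average observer can distinguish.

Pair classification uses the JND thresholds:

* ``indistinguishable`` — dE00 <  1 JND (strictly below 2.3),
* ``difficult``         — 1 JND <= dE00 <= 3 JND (2.3 to 6.9 inclusive),
* ``discriminable``     — dE00 >  3 JND.

The strict lower boundary matters in practice: a pair at dE00 = 2.33 is
counted as difficult, not indistinguishable.

The central object is the confusion matrix: the symmetric n x n matrix of
pairwise dE00 values between all colours of a scale as perceived under a
given (simulated) vision condition. Sweeping the severity k over its grid
yields summary curves (median and minimum dE00, pair counts within 1 and 3
JND) that quantify how discriminability degrades from regular vision (k = 1)
to dichromacy (k = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import Illuminant, xyz_to_lab
from .cvd import DEFICIENCIES, k_grid, simulate_deficiency
from .scale import ColourScale

__all__ = [
    "JND_DELTA_E",
    "PAIR_CLASSES",
    "delta_e00",
    "ConfusionMatrix",
    "PairSummary",
    "confusion_matrix",
    "classify_pairs",
    "indistinguishable_pairs",
    "summarize",
    "k_sweep",
    "percent_reduction",
]

#: One just-noticeable difference expressed in dE00 units.
JND_DELTA_E = 2.3

PAIR_CLASSES = ("indistinguishable", "difficult", "discriminable")


def delta_e00(lab_a, lab_b) -> np.ndarray | float:
    """CIEDE2000 colour difference between L*a*b* colours.

    Implements the full formula (lightness, chroma and hue weighting plus the
    blue-region rotation term) with kL = kC = kH = 1. Broadcasts over leading
    axes; scalar inputs give a scalar. Symmetric, non-negative, and zero
    exactly when the two Lab triplets are identical.
    """
    a = np.asarray(lab_a, dtype=float)
    b = np.asarray(lab_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite Lab input to delta_e00")
    L1, a1, b1 = a[..., 0], a[..., 1], a[..., 2]
    L2, a2, b2 = b[..., 0], b[..., 1], b[..., 2]

    c1 = np.hypot(a1, b1)
    c2 = np.hypot(a2, b2)
    cbar = 0.5 * (c1 + c2)
    c7 = cbar**7
    g = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + g) * a1
    a2p = (1.0 + g) * a2
    c1p = np.hypot(a1p, b1)
    c2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((b1 == 0) & (a1p == 0), 0.0, h1p)
    h2p = np.where((b2 == 0) & (a2p == 0), 0.0, h2p)

    dLp = L2 - L1
    dCp = c2p - c1p

    zero_chroma = (c1p * c2p) == 0
    dhp = h2p - h1p
    dhp = np.where(dhp > 180.0, dhp - 360.0, dhp)
    dhp = np.where(dhp < -180.0, dhp + 360.0, dhp)
    dhp = np.where(zero_chroma, 0.0, dhp)
    dHp = 2.0 * np.sqrt(c1p * c2p) * np.sin(np.radians(dhp) / 2.0)

    Lbar = 0.5 * (L1 + L2)
    cbarp = 0.5 * (c1p + c2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbar = np.where(
        zero_chroma,
        hsum,  # Sharma convention: with a zero-chroma member, hbar = h1'+h2'
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    t = (
        1.0
        - 0.17 * np.cos(np.radians(hbar - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbar))
        + 0.32 * np.cos(np.radians(3.0 * hbar + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbar - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbar - 275.0) / 25.0) ** 2))
    cbarp7 = cbarp**7
    rc = 2.0 * np.sqrt(cbarp7 / (cbarp7 + 25.0**7))
    sl = 1.0 + 0.015 * (Lbar - 50.0) ** 2 / np.sqrt(20.0 + (Lbar - 50.0) ** 2)
    sc = 1.0 + 0.045 * cbarp
    sh = 1.0 + 0.015 * cbarp * t
    rt = -np.sin(np.radians(2.0 * dtheta)) * rc

    term_l = dLp / sl
    term_c = dCp / sc
    term_h = dHp / sh
    out = np.sqrt(term_l**2 + term_c**2 + term_h**2 + rt * term_c * term_h)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Symmetric pairwise dE00 matrix over a colour scale."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n), symmetric, zero diagonal
    deficiency: str  # one of DEFICIENCIES or "regular"
    severity_k: float
    illuminant: Illuminant

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_values(self) -> np.ndarray:
        """dE00 of the n(n-1)/2 unordered off-diagonal pairs."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def in_jnd_units(self) -> np.ndarray:
        return self.values / JND_DELTA_E

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


class PairSummary(NamedTuple):
    """Summary statistics over unordered off-diagonal pairs."""

    median: float
    minimum: float
    n_within_1jnd: int  # dE00 < 2.3: indistinguishable pairs
    n_within_3jnd: int  # dE00 <= 6.9: pairs at best difficult to tell apart


def confusion_matrix(
    scale: ColourScale,
    deficiency: str = "regular",
    severity_k: float = 1.0,
) -> ConfusionMatrix:
    """Pairwise dE00 between all scale colours under a vision condition.

    The colours are passed through the deficiency simulation (skipped for
    ``"regular"``), converted to L*a*b* against the white point of the
    scale's own illuminant, and compared pairwise with CIEDE2000.
    """
    if deficiency == "regular":
        xyz = scale.xyz.copy()
        severity_k = 1.0
    else:
        xyz = simulate_deficiency(scale.xyz, deficiency, severity_k)
    lab = xyz_to_lab(xyz, scale.illuminant)
    values = delta_e00(lab[:, None, :], lab[None, :, :])
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    np.fill_diagonal(values, 0.0)
    return ConfusionMatrix(
        labels=scale.labels,
        values=values,
        deficiency=deficiency,
        severity_k=float(severity_k),
        illuminant=scale.illuminant,
    )


def classify_pairs(matrix: ConfusionMatrix) -> dict[tuple[str, str], str]:
    """Classify every unordered pair by its dE00 in JND units.

    Boundaries: strictly below 1 JND is ``indistinguishable``; from 1 JND to
    3 JND inclusive is ``difficult``; above 3 JND is ``discriminable``.
    """
    out: dict[tuple[str, str], str] = {}
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            # classify in JND units so the 3-JND boundary (raw 6.9) does not
            # fall foul of 3 * 2.3 != 6.9 in binary floating point
            jnd = matrix.values[i, j] / JND_DELTA_E
            if jnd < 1.0:
                cls = "indistinguishable"
            elif jnd <= 3.0 + 1e-9:  # epsilon: raw 6.9 is exactly 3 JND
                cls = "difficult"
            else:
                cls = "discriminable"
            out[(matrix.labels[i], matrix.labels[j])] = cls
    return out


def indistinguishable_pairs(matrix: ConfusionMatrix) -> set[tuple[str, str]]:
    """Unordered pairs strictly below 1 JND."""
    return {
        pair
        for pair, cls in classify_pairs(matrix).items()
        if cls == "indistinguishable"
    }


def summarize(matrix: ConfusionMatrix) -> PairSummary:
    """Median/minimum dE00 and JND pair counts over unordered pairs.

    The diagonal (self-pairs, identically zero) is excluded so it cannot
    bias the statistics; with n colours there are n(n-1)/2 pairs.
    """
    if matrix.n < 2:
        raise ValueError("summary requires at least 2 colours")
    pairs = matrix.pair_values()
    jnd = pairs / JND_DELTA_E
    return PairSummary(
        median=float(np.median(pairs)),
        minimum=float(pairs.min()),
        n_within_1jnd=int(np.count_nonzero(jnd < 1.0)),
        n_within_3jnd=int(np.count_nonzero(jnd <= 3.0 + 1e-9)),
    )


def k_sweep(
    scale: ColourScale,
    deficiencies=DEFICIENCIES,
    step: float = 0.01,
) -> pd.DataFrame:
    """Summary statistics across the full severity grid.

    Returns a long-format frame with columns ``deficiency, k, median, min,
    n_lt_1jnd, n_le_3jnd``, one row per (deficiency, k) with k running from
    1 down to 0. At k = 1 every deficiency reproduces the regular-vision
    summary.
    """
    rows = []
    for deficiency in deficiencies:
        for k in k_grid(step):
            s = summarize(confusion_matrix(scale, deficiency, float(k)))
            rows.append(
                {
                    "deficiency": deficiency,
                    "k": float(k),
                    "median": s.median,
                    "min": s.minimum,
                    "n_lt_1jnd": s.n_within_1jnd,
                    "n_le_3jnd": s.n_within_3jnd,
                }
            )
    return pd.DataFrame(rows)


def percent_reduction(sweep: pd.DataFrame, deficiency: str) -> float:
    """Worst-case reduction of the median pair dE00, as a percentage.

    100 x (median at k=1 minus the smallest median over the grid) divided by
    the median at k=1. The sweep must contain k = 1 and k = 0 for the
    requested deficiency.
    """
    sub = sweep[sweep["deficiency"] == deficiency]
    if sub.empty or 1.0 not in sub["k"].values or 0.0 not in sub["k"].values:
        raise ValueError(f"sweep lacks k=1 and k=0 rows for {deficiency!r}")
    baseline = float(sub.loc[sub["k"] == 1.0, "median"].iloc[0])
    if baseline == 0:
        raise ValueError("baseline median is zero; reduction undefined")
    worst = float(sub["median"].min())
    return 100.0 * (baseline - worst) / baseline
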