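"""Discrete colour scales: loading, validation, illuminant adaptation, I/O.

A :class:`ColourScale` is an ordered list of named colours (XYZ tristimulus
values) together with the illuminant they are expressed under. The bundled
"forel-ule" scale is a 21-step water-colour scale running from indigo blue
(FU 1) through green (FU 11) to cola brown (FU 21), defined under the
equal-energy illuminant E.

The bundled table (``data/forel_ule_synthetic.csv``) is a synthetic
reconstruction: the measured tristimulus values of the physical Forel-Ule
standard are published elsewhere and are not reproduced here, so the fixture
was built once from the scale's documented structure (hue-angle progression
around the white point, saturation and lightness profiles). It is
version-pinned by checksum; see the file header and the methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Illuminant, chromatic_adapt, get_illuminant, srgb_hex

__all__ = [
    "ColourScale",
    "load_scale",
    "save_scale",
    "adapt_scale",
    "scale_to_json",
    "FU_FIXTURE_SHA256",
]

# Pinned checksum of the bundled 21-colour Forel-Ule reconstruction.
FU_FIXTURE_SHA256 = "4e1c97c147e9f7625df444138c70d39ac0eb849204fc7015a22754e567332796"

_FU_RESOURCE = "forel_ule_synthetic.csv"


@dataclass(frozen=True)
class ColourScale:
    """An ordered, named set of XYZ colours under a stated illuminant."""

    name: str
    labels: tuple[str, ...]
    xyz: np.ndarray  # shape (n, 3)
    illuminant: Illuminant

    def __post_init__(self):
        arr = np.asarray(self.xyz, dtype=float)
        labels = tuple(str(l) for l in self.labels)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"scale colours must be (n, 3), got {arr.shape}")
        if len(labels) != arr.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {arr.shape[0]} colours in scale {self.name!r}"
            )
        if len(labels) < 2:
            raise ValueError(f"scale {self.name!r} needs at least 2 colours")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise ValueError(f"duplicate label {lab!r} in scale {self.name!r}")
            seen.add(lab)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite tristimulus value in scale {self.name!r}")
        if np.any(arr < 0):
            bad = labels[int(np.argwhere(np.any(arr < 0, axis=1))[0, 0])]
            raise ValueError(f"negative tristimulus value at label {bad!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "xyz", arr)
        object.__setattr__(self, "illuminant", get_illuminant(self.illuminant))

    def __len__(self) -> int:
        return len(self.labels)

    def with_colours(self, xyz: np.ndarray, illuminant=None) -> "ColourScale":
        return replace(
            self,
            xyz=np.asarray(xyz, dtype=float),
            illuminant=get_illuminant(illuminant) if illuminant is not None else self.illuminant,
        )


def _read_scale_csv(path: Path, illuminant: str | Illuminant, name: str) -> ColourScale:
    try:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"cannot parse scale CSV {path}: {exc}") from exc
    required = ["label", "X", "Y", "Z"]
    if list(frame.columns[:4]) != required:
        raise ValueError(
            f"scale CSV {path} must start with header {','.join(required)}, "
            f"got {list(frame.columns)}"
        )
    for col in ("X", "Y", "Z"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = frame.loc[vals.isna(), "label"].iloc[0]
            raise ValueError(f"non-numeric {col} value at label {row!r} in {path}")
        frame[col] = vals
    return ColourScale(
        name=name,
        labels=tuple(str(l) for l in frame["label"]),
        xyz=frame[["X", "Y", "Z"]].to_numpy(float),
        illuminant=get_illuminant(illuminant),
    )


def fu_fixture_path() -> Path:
    """Filesystem path of the bundled Forel-Ule reconstruction."""
    return Path(resources.files("cvdscale").joinpath("data", _FU_RESOURCE))


def fu_fixture_checksum() -> str:
    """SHA-256 of the bundled fixture file as shipped."""
    return hashlib.sha256(fu_fixture_path().read_bytes()).hexdigest()


def load_scale(source: str | Path, illuminant: str | Illuminant = "E") -> ColourScale:
    """Load a colour scale from CSV, or the builtin token ``"forel-ule"``.

    CSV format: header ``label,X,Y,Z``, comma separated, period decimal
    marker; lines starting with ``#`` are comments. The builtin Forel-Ule
    scale is tagged with illuminant E (the illuminant it is defined under)
    regardless of the ``illuminant`` argument.
    """
    if isinstance(source, str) and source.lower() in ("forel-ule", "fu"):
        scale = _read_scale_csv(fu_fixture_path(), "E", name="forel-ule")
        if len(scale) != 21:
            raise ValueError("bundled forel-ule fixture must have exactly 21 entries")
        if fu_fixture_checksum() != FU_FIXTURE_SHA256:
            raise ValueError(
                "bundled forel-ule fixture does not match its pinned checksum"
            )
        return scale
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"scale source {source!r} not found")
    return _read_scale_csv(path, illuminant, name=path.stem)


def save_scale(scale: ColourScale, path: str | Path) -> Path:
    """Write a scale to CSV (header ``label,X,Y,Z``), full float precision."""
    path = Path(path)
    lines = ["label,X,Y,Z\n"]
    for label, (x, y, z) in zip(scale.labels, scale.xyz):
        # repr = shortest round-trip float formatting: bit-exact reload
        lines.append(f"{label},{float(x)!r},{float(y)!r},{float(z)!r}\n")
    path.write_text("".join(lines))
    return path


def adapt_scale(scale: ColourScale, target: str | Illuminant) -> ColourScale:
    """Chromatically adapt every colour of a scale to a target illuminant.

    Order, labels and length are preserved; only the tristimulus values and
    the illuminant tag change. Adapting to the current illuminant returns an
    identical copy.
    """
    dst = get_illuminant(target)
    adapted = chromatic_adapt(scale.xyz, scale.illuminant, dst)
    return scale.with_colours(adapted, illuminant=dst)


def scale_to_json(scale: ColourScale) -> str:
    """JSON export with illuminant metadata and display swatches.

    Swatches are sRGB hex strings of the colours adapted to D65 (display
    white); they are for visualisation only.
    """
    display = adapt_scale(scale, "D65")
    payload = {
        "name": scale.name,
        "illuminant": scale.illuminant.name,
        "colours": [
            {
                "label": lab,
                "X": float(x),
                "Y": float(y),
                "Z": float(z),
                "srgb_hex": str(hexcode),
            }
            for lab, (x, y, z), hexcode in zip(
                scale.labels, scale.xyz, srgb_hex(display.xyz)
            )
        ],
    }
    return json.dumps(payload, indent=2)
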