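"""Full-analysis orchestration: one call reproduces every table of the audit.

``run_full_analysis`` takes a scale (bundled or user CSV), simulates all
three deficiency families over the full severity grid, and writes a bundle
of machine-readable outputs:

* ``swatches.csv`` — display sRGB hex of every scale colour per deficiency
  at k = 1, 0.5, 0 (appearance table; D65-adapted, swatch use only);
* ``lab_coordinates.csv`` — L*a*b* coordinates of the (simulated) colours;
* ``confusion_<condition>.csv`` — pairwise dE00 matrices, raw and in JND
  units, for regular vision and each dichromatic endpoint;
* ``sweep.csv`` — long-format summary statistics over the severity grid;
* ``headline.json`` — the headline numbers (medians, minima, pair counts,
  indistinguishable pairs, percent reductions), with raw values and
  printed-precision roundings reported separately, plus provenance (input
  checksum and configuration echo).

All outputs are deterministic and written atomically (temp file + rename),
so repeated runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import chromatic_adapt, srgb_hex, xyz_to_lab
from .cvd import DEFICIENCIES, simulate_deficiency
from .metrics import (
    JND_DELTA_E,
    confusion_matrix,
    indistinguishable_pairs,
    k_sweep,
    percent_reduction,
    summarize,
)
from .scale import ColourScale, adapt_scale, fu_fixture_checksum, load_scale

__all__ = ["AnalysisConfig", "run_full_analysis"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full audit run."""

    scale_source: str = "forel-ule"
    illuminant: str | None = None  # None: analyse under the scale's own illuminant
    deficiencies: tuple[str, ...] = DEFICIENCIES
    k_step: float = 0.01
    swatch_severities: tuple[float, ...] = (1.0, 0.5, 0.0)
    out_dir: str | Path = "cvdscale-report"


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_csv(frame: pd.DataFrame, **kwargs) -> str:
    return frame.to_csv(float_format="%.9g", lineterminator="\n", **kwargs)


def _conditions(config: AnalysisConfig):
    yield "regular", "regular", 1.0
    for d in config.deficiencies:
        yield f"{d}_k0", d, 0.0


def run_full_analysis(config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run the complete audit and write the report bundle.

    Returns the headline dictionary (also written to ``headline.json``).
    Raises ``OSError`` before any computation if the output directory cannot
    be created or written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write-probe"
    probe.touch()
    probe.unlink()

    scale = load_scale(config.scale_source)
    source_checksum = (
        fu_fixture_checksum()
        if str(config.scale_source).lower() in ("forel-ule", "fu")
        else hashlib.sha256(Path(config.scale_source).read_bytes()).hexdigest()
    )
    if config.illuminant is not None:
        scale = adapt_scale(scale, config.illuminant)

    # (a) appearance swatches at selected severities, D65-adapted for display
    swatch_rows = []
    lab_rows = []
    for deficiency in ("regular",) + tuple(config.deficiencies):
        for k in config.swatch_severities:
            if deficiency == "regular" and k != 1.0:
                continue
            xyz = (
                scale.xyz
                if deficiency == "regular"
                else simulate_deficiency(scale.xyz, deficiency, k)
            )
            hexes = srgb_hex(chromatic_adapt(xyz, scale.illuminant, "D65"))
            lab = xyz_to_lab(xyz, scale.illuminant)
            for label, h, (L, a, b) in zip(scale.labels, hexes, lab):
                swatch_rows.append(
                    {"deficiency": deficiency, "k": k, "label": label, "srgb_hex": h}
                )
                lab_rows.append(
                    {
                        "deficiency": deficiency,
                        "k": k,
                        "label": label,
                        "L_star": L,
                        "a_star": a,
                        "b_star": b,
                    }
                )
    _atomic_write(out / "swatches.csv", _frame_csv(pd.DataFrame(swatch_rows), index=False))
    _atomic_write(
        out / "lab_coordinates.csv", _frame_csv(pd.DataFrame(lab_rows), index=False)
    )

    # (c) confusion matrices, raw dE00 and JND units
    matrices = {}
    for tag, deficiency, k in _conditions(config):
        cm = confusion_matrix(scale, deficiency, k)
        matrices[tag] = cm
        _atomic_write(out / f"confusion_{tag}.csv", _frame_csv(cm.to_frame()))
        jnd = cm.to_frame() / JND_DELTA_E
        _atomic_write(out / f"confusion_{tag}_jnd.csv", _frame_csv(jnd))

    # (d) severity sweep and headline numbers
    sweep = k_sweep(scale, config.deficiencies, config.k_step)
    _atomic_write(out / "sweep.csv", _frame_csv(sweep, index=False))

    regular = summarize(matrices["regular"])
    headline: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": {
            "scale_source": str(config.scale_source),
            "scale_sha256": source_checksum,
            "illuminant": scale.illuminant.name,
            "k_step": config.k_step,
            "n_colours": len(scale),
            "jnd_delta_e00": JND_DELTA_E,
        },
        "regular": {
            "median_delta_e00": regular.median,
            "min_delta_e00": regular.minimum,
            "n_pairs_within_1jnd": regular.n_within_1jnd,
            "n_pairs_within_3jnd": regular.n_within_3jnd,
            "rounded": {
                "median": round(regular.median),
                "min": round(regular.minimum, 1),
            },
        },
        "deficiencies": {},
    }
    for d in config.deficiencies:
        cm0 = matrices[f"{d}_k0"]
        s0 = summarize(cm0)
        sub = sweep[sweep["deficiency"] == d]
        with_confusions = sub.loc[sub["n_lt_1jnd"] > 0, "k"]
        headline["deficiencies"][d] = {
            "median_delta_e00_k0": s0.median,
            "min_delta_e00_k0": s0.minimum,
            "n_pairs_within_1jnd_k0": s0.n_within_1jnd,
            "n_pairs_within_3jnd_k0": s0.n_within_3jnd,
            "indistinguishable_pairs_k0": sorted(
                list(p) for p in indistinguishable_pairs(cm0)
            ),
            "median_percent_reduction": percent_reduction(sweep, d),
            "largest_k_with_pair_below_1jnd": (
                float(with_confusions.max()) if len(with_confusions) else None
            ),
            "rounded": {
                "median_k0": round(s0.median),
                "min_k0": round(s0.minimum, 1),
                "median_percent_reduction": round(percent_reduction(sweep, d)),
            },
        }
    _atomic_write(
        out / "headline.json", json.dumps(headline, indent=2, sort_keys=True) + "\n"
    )
    return headline
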