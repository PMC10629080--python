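"""Intrinsic hydrophobicity scales.

The observed-hydrophobicity field weighs every residue pair by the sum of the
two residues' intrinsic hydrophobicities, so the whole analysis is
parameterised by one 20-value table.  The table is pluggable: any mapping of
3-letter codes to values in [0, 1] is accepted, and a plain two-column text
format is supported for user-supplied scales.

The shipped default is the Kyte–Doolittle hydropathy index rescaled linearly
to [0, 1] (ILE = 1, ARG = 0).  Published FOD analyses use their own
calibration, which is not public; quantitative agreement with such results
therefore depends on supplying the matching scale file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

__all__ = [
    "KD_NORMALIZED",
    "default_scale",
    "load_scale",
    "normalize_scale",
    "STANDARD_AMINO_ACIDS",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Kyte & Doolittle hydropathy, raw values in [-4.5, 4.5].
_KD_RAW = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


def normalize_scale(raw: Mapping[str, float]) -> dict[str, float]:
    """Min–max rescale a residue->value mapping onto [0, 1]."""
    lo = min(raw.values())
    hi = max(raw.values())
    if hi == lo:
        raise ValueError("scale is constant; cannot normalize")
    return {res: (val - lo) / (hi - lo) for res, val in raw.items()}


KD_NORMALIZED: dict[str, float] = normalize_scale(_KD_RAW)


def default_scale() -> dict[str, float]:
    """A fresh copy of the default normalized hydropathy scale."""
    return dict(KD_NORMALIZED)


def load_scale(path: str | Path) -> dict[str, float]:
    """Read a two-column scale file: ``<3-letter code> <value in [0,1]>``.

    Blank lines and ``#`` comments are ignored.  All 20 standard amino acids
    must be present; values outside [0, 1] are rejected.
    """
    scale: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected '<code> <value>', got {line!r}")
        code, value = parts[0].upper(), float(parts[1])
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{path}:{lineno}: value {value} outside [0, 1]")
        scale[code] = value
    missing = STANDARD_AMINO_ACIDS - scale.keys()
    if missing:
        raise ValueError(f"scale file {path} missing residues: {sorted(missing)}")
    return scale
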