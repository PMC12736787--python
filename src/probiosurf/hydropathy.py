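"""Kyte-Doolittle hydropathy: per-residue values, window means, GRAVY.

GRAVY (grand average of hydropathy) is the arithmetic mean of per-residue
hydropathy values. Ambiguity letters (X/B/Z) and selenocysteine (U) are
excluded from both numerator and denominator rather than scored as 0, which
would bias X-rich draft annotations toward apparent hydrophilicity; the
count of scored residues is always available alongside the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

# Kyte & Doolittle (1982) reference hydropathy values, dimensionless.
_KD_VALUES: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


class UndefinedGravyError(ValueError):
    """Raised when a sequence contains no scorable (canonical) residue."""


@dataclass(frozen=True)
class HydropathyScale:
    """A per-residue hydropathy scale over the 20 canonical amino acids."""

    values: Mapping[str, float]
    name: str = "kyte-doolittle"

    def __post_init__(self) -> None:
        if set(self.values) != set(_KD_VALUES):
            missing = set(_KD_VALUES) - set(self.values)
            extra = set(self.values) - set(_KD_VALUES)
            raise ValueError(
                f"scale must cover exactly the 20 canonical residues "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def lookup_table(self) -> np.ndarray:
        """256-entry float table keyed by ASCII code; NaN for unscored letters."""
        table = np.full(256, np.nan)
        for aa, val in self.values.items():
            table[ord(aa)] = val
            table[ord(aa.lower())] = val
        return table

    def to_json_dict(self) -> dict:
        return {"name": self.name, "values": dict(self.values)}


KYTE_DOOLITTLE = HydropathyScale(values=_KD_VALUES, name="kyte-doolittle")
_KD_TABLE = KYTE_DOOLITTLE.lookup_table()


def _residue_values(sequence: str, scale: HydropathyScale) -> np.ndarray:
    """Per-position scale values; NaN at ambiguous/rare letters (X/B/Z/U)."""
    table = _KD_TABLE if scale is KYTE_DOOLITTLE else scale.lookup_table()
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return table[codes]


def gravy(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """GRAVY: mean hydropathy over the canonical residues of ``sequence``.

    X/B/Z/U are excluded from numerator and denominator. Raises
    :class:`UndefinedGravyError` if no canonical residue remains.
    """
    vals = _residue_values(sequence, scale)
    mask = ~np.isnan(vals)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedGravyError("sequence contains no canonical residue")
    return float(vals[mask].sum() / n)


def n_scored_residues(sequence: str, scale: HydropathyScale = KYTE_DOOLITTLE) -> int:
    """Number of canonical residues that contribute to GRAVY."""
    return int((~np.isnan(_residue_values(sequence, scale))).sum())


def window_mean(
    sequence: str,
    start: int,
    width: int,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> float:
    """Mean hydropathy of the 1-based window ``[start, start+width-1]``.

    Same ambiguity-exclusion rule as :func:`gravy`.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if start < 1 or start + width - 1 > len(sequence):
        raise IndexError(
            f"window [{start}, {start + width - 1}] out of range for length {len(sequence)}"
        )
    return gravy(sequence[start - 1 : start - 1 + width], scale)


def sliding_window_means(
    sequence: str, width: int, scale: HydropathyScale = KYTE_DOOLITTLE
) -> np.ndarray:
    """Mean hydropathy of every width-``width`` window (NaN-excluding), vectorized.

    Entry ``i`` (0-based) is the mean over 1-based window starting at ``i+1``.
    Windows whose canonical-residue count is 0 yield NaN.
    """
    vals = _residue_values(sequence, scale)
    if len(vals) < width:
        return np.empty(0)
    finite = np.where(np.isnan(vals), 0.0, vals)
    counts = (~np.isnan(vals)).astype(float)
    kernel = np.ones(width)
    sums = np.convolve(finite, kernel, mode="valid")
    ns = np.convolve(counts, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ns > 0, sums / ns, np.nan)


def gravy_mature(
    sequence: str, cleavage_pos: int, scale: HydropathyScale = KYTE_DOOLITTLE
) -> float:
    """GRAVY of the mature chain: residues ``cleavage_pos+1 .. end`` (1-based).

    ``cleavage_pos`` is the last residue of the signal peptide; it must leave
    a nonempty mature chain.
    """
    if not 1 <= cleavage_pos < len(sequence):
        raise ValueError(
            f"cleavage position {cleavage_pos} leaves no mature chain "
            f"(length {len(sequence)})"
        )
    return gravy(sequence[cleavage_pos:], scale)
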