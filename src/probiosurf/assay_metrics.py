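"""Phenotypic assay calculators: biofilm class, aggregation and BATS percentages.

All calculators are exact arithmetic on the supplied optical densities; the
only aggregation applied is the arithmetic mean over replicates, taken before
classification (standard deviations are carried for reporting only and never
affect a class). Negative percentages are meaningful — a negative
adhesion-to-toluene, for example, indicates a hydrophilic cell surface — and
are reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

BIOFILM_CLASSES = ("Negative", "Weak", "Moderate", "Strong")


@dataclass(frozen=True)
class PlateReadings:
    """Replicate OD readings for test wells and negative-control wells."""

    od_test: tuple[float, ...]
    od_control: tuple[float, ...]
    wavelength_nm: int = 630

    def __post_init__(self) -> None:
        if len(self.od_test) < 1 or len(self.od_control) < 1:
            raise ValueError("need at least one replicate per group")
        if any(od < 0 for od in self.od_test + self.od_control):
            raise ValueError("optical densities must be >= 0")


@dataclass(frozen=True)
class BiofilmResult:
    odc_mean: float
    odt_mean: float
    odc_sd: float
    odt_sd: float
    fold_ratio: float
    biofilm_class: str

    def to_dict(self) -> dict:
        return asdict(self)


def classify_od_ratio(odt_mean: float, odc_mean: float) -> str:
    """Four-level crystal-violet class with inclusive upper boundaries.

    Negative: ODt <= ODc; Weak: ODc < ODt <= 2*ODc;
    Moderate: 2*ODc < ODt <= 4*ODc; Strong: ODt > 4*ODc.
    """
    if odc_mean <= 0:
        raise ValueError("control mean OD must be > 0 (ratio undefined)")
    if odt_mean <= odc_mean:
        return "Negative"
    if odt_mean <= 2 * odc_mean:
        return "Weak"
    if odt_mean <= 4 * odc_mean:
        return "Moderate"
    return "Strong"


def biofilm_classify(readings: PlateReadings) -> BiofilmResult:
    """Mean the replicates and classify biofilm production."""
    odt = np.asarray(readings.od_test, dtype=float)
    odc = np.asarray(readings.od_control, dtype=float)
    odt_mean, odc_mean = float(odt.mean()), float(odc.mean())
    cls = classify_od_ratio(odt_mean, odc_mean)
    return BiofilmResult(
        odc_mean=odc_mean,
        odt_mean=odt_mean,
        odc_sd=float(odc.std(ddof=1)) if odc.size > 1 else 0.0,
        odt_sd=float(odt.std(ddof=1)) if odt.size > 1 else 0.0,
        fold_ratio=odt_mean / odc_mean,
        biofilm_class=cls,
    )


def autoaggregation_pct(od_initial: float, od_final: float) -> float:
    """Autoaggregation percentage: ``(initial - final) / initial * 100``.

    Negative when the suspension reads denser at the end; reported as-is.
    """
    if od_initial <= 0:
        raise ValueError("initial OD must be > 0")
    return (od_initial - od_final) / od_initial * 100.0


def coaggregation_pct(ax: float, ay: float, amix: float) -> float:
    """Coaggregation percentage of a LAB-pathogen mixture.

    ``100 * ((Ax + Ay)/2 - Amix) / ((Ax + Ay)/2)`` — symmetric in the two
    single-strain absorbances.
    """
    pair_mean = (ax + ay) / 2.0
    if pair_mean <= 0:
        raise ValueError("Ax + Ay must be > 0")
    return (pair_mean - amix) / pair_mean * 100.0


def bats_adhesion_pct(a0: float, a: float) -> float:
    """Bacterial-adhesion-to-solvents percentage: ``(1 - A/A0) * 100``.

    ``A0`` is the aqueous-phase absorbance before solvent addition, ``A``
    after phase separation. Negative values (surface repelled by the solvent)
    are reported unclamped.
    """
    if a0 <= 0:
        raise ValueError("A0 must be > 0")
    return (1.0 - a / a0) * 100.0
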