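"""Heuristic surface-localization classifier for Gram-positive proteomes.

Three sequence heuristics, mirroring the canonical biology of surface
exposure in lactic acid bacteria:

* **secreted** — a Sec-type signal peptide: an N-terminal hydrophobic
  stretch followed by an A-X-A signal-peptidase-I cleavage site;
* **lipoprotein** — a lipobox ``L[AS][AG]C`` whose conserved Cys (the lipid
  anchor) sits near the end of a signal-peptide-like N-terminus;
* **lpxtg_anchored** — a C-terminal LPXTG sortase motif followed by a
  transmembrane stretch and a positively charged (K/R-rich) tail.

Every span and threshold is a tunable :class:`ClassifierParams` field; the
defaults target canonical Gram-positive signal peptides (~20-35 aa with a
hydrophobic core of >= 8 residues) and sortase anchors (~30-40 residues from
the C-terminus). Categories are mutually exclusive with precedence
lpxtg_anchored > lipoprotein > secreted, anchored forms being the most
specific evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from probiosurf.hydropathy import (
    HydropathyScale,
    KYTE_DOOLITTLE,
    gravy,
    sliding_window_means,
)
from probiosurf.proteome_io import ProteinRecord, Proteome

CATEGORIES = ("lpxtg_anchored", "lipoprotein", "secreted", "none")

_LIPOBOX_RE = re.compile(r"L[AS][AG]C")
_LPXTG_RE = re.compile(r"LP.TG")


@dataclass(frozen=True)
class ClassifierParams:
    """Spans and thresholds of the three surface heuristics.

    Units are residues for spans/positions and Kyte-Doolittle hydropathy
    (dimensionless) for thresholds; all positions are 1-based.
    """

    sp_scan_len: int = 45      # N-terminal span scanned for the hydrophobic window
    h_window: int = 8          # hydrophobic-window width
    h_thresh: float = 1.5      # mean-hydropathy threshold for hydrophobic windows
    sp_cleave_min: int = 15    # earliest allowed cleavage position
    sp_cleave_max: int = 45    # latest allowed cleavage position
    lipobox_c_min: int = 15    # earliest allowed lipobox Cys position
    lipobox_c_max: int = 40    # latest allowed lipobox Cys position
    lpxtg_c_window: int = 50   # C-terminal span searched for LPXTG
    tm_window: int = 15        # transmembrane-window width after the LPXTG motif
    tail_len: int = 10         # charged-tail span at the C-terminus
    tail_min_kr: int = 2       # minimum K/R count in the tail

    def __post_init__(self) -> None:
        for name in (
            "sp_scan_len", "h_window", "sp_cleave_min", "sp_cleave_max",
            "lipobox_c_min", "lipobox_c_max", "lpxtg_c_window", "tm_window",
            "tail_len", "tail_min_kr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sp_cleave_min > self.sp_cleave_max:
            raise ValueError("sp_cleave_min must be <= sp_cleave_max")
        if self.lipobox_c_min > self.lipobox_c_max:
            raise ValueError("lipobox_c_min must be <= lipobox_c_max")
        if not np.isfinite(self.h_thresh):
            raise ValueError("h_thresh must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, path: str | Path) -> "ClassifierParams":
        """Read params from a flat ``key: value`` (or ``key=value``) text file."""
        kwargs: dict[str, float] = {}
        valid = set(cls.__dataclass_fields__)
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in (":", "="):
                if sep in line:
                    key, _, value = line.partition(sep)
                    break
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            typ = float if key == "h_thresh" else int
            kwargs[key] = typ(value.strip())
        return cls(**kwargs)


@dataclass(frozen=True)
class SignalPeptideCall:
    """Evidence for a Sec signal peptide (all positions 1-based)."""

    h_start: int          # hydrophobic window start
    h_end: int            # hydrophobic window end
    cleavage_pos: int     # last signal-peptide residue (second A of A-X-A)
    sp_mean_kd: float     # mean hydropathy of residues 1..cleavage_pos

    def __post_init__(self) -> None:
        if not (self.h_start <= self.h_end < self.cleavage_pos):
            raise ValueError("require h_start <= h_end < cleavage_pos")


@dataclass(frozen=True)
class SurfaceCall:
    """Per-protein localization verdict with the detector evidence retained."""

    protein_id: str
    category: str
    signal_peptide: Optional[SignalPeptideCall] = None
    lipobox_pos: Optional[int] = None
    lpxtg_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "secreted" and self.signal_peptide is None:
            raise ValueError("secreted call requires a signal peptide")
        if self.category == "lipoprotein" and self.lipobox_pos is None:
            raise ValueError("lipoprotein call requires a lipobox position")
        if self.category == "lpxtg_anchored" and self.lpxtg_pos is None:
            raise ValueError("lpxtg_anchored call requires a motif position")

    @property
    def is_surface(self) -> bool:
        return self.category != "none"


def _first_hydrophobic_window(
    seq: str, params: ClassifierParams, scale: HydropathyScale
) -> Optional[tuple[int, int]]:
    """1-based (start, end) of the first qualifying N-terminal hydrophobic window."""
    means = sliding_window_means(seq, params.h_window, scale)
    limit = min(params.sp_scan_len, len(means))  # window must start within scan span
    for i in range(limit):
        if means[i] >= params.h_thresh:
            return i + 1, i + params.h_window
    return None


def detect_signal_peptide(
    record: ProteinRecord,
    params: ClassifierParams = ClassifierParams(),
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> Optional[SignalPeptideCall]:
    """Detect a Sec-type signal peptide; ``None`` when absent.

    Requires (i) a hydrophobic window (width ``h_window``, mean KD >=
    ``h_thresh``) starting within the first ``sp_scan_len`` residues, and
    (ii) an A-X-A triplet whose second A lies in
    ``[max(sp_cleave_min, h_end+1), sp_cleave_max]``. The cleavage site is
    the first qualifying triplet after the first qualifying window.
    """
    seq = record.sequence
    if len(seq) < params.sp_cleave_min:
        return None
    window = _first_hydrophobic_window(seq, params, scale)
    if window is None:
        return None
    h_start, h_end = window
    lo = max(params.sp_cleave_min, h_end + 1)
    hi = min(params.sp_cleave_max, len(seq))
    # scan A-X-A triplets by the position of the second A (1-based j+2)
    for end in range(lo, hi + 1):
        if end - 2 >= 1 and seq[end - 1] == "A" and seq[end - 3] == "A":
            return SignalPeptideCall(
                h_start=h_start,
                h_end=h_end,
                cleavage_pos=end,
                sp_mean_kd=gravy(seq[:end], scale),
            )
    return None


def detect_lipobox(
    record: ProteinRecord,
    sp_context: Optional[SignalPeptideCall] = None,
    params: ClassifierParams = ClassifierParams(),
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> Optional[int]:
    """1-based position of the lipobox leucine, or ``None``.

    Matches ``L[AS][AG]C`` with the Cys in ``[lipobox_c_min, lipobox_c_max]``
    and an N-terminal hydrophobic window (criterion (i) of the signal-peptide
    heuristic) ending before the Cys. A full signal-peptide call is not
    required — lipoprotein signal peptides end in the lipobox itself, not in
    an A-X-A site.
    """
    seq = record.sequence
    if sp_context is not None:
        window: Optional[tuple[int, int]] = (sp_context.h_start, sp_context.h_end)
    else:
        window = _first_hydrophobic_window(seq, params, scale)
    if window is None:
        return None
    _, h_end = window
    for m in _LIPOBOX_RE.finditer(seq):
        cys_pos = m.start() + 4  # 1-based position of C in L[AS][AG]C
        if params.lipobox_c_min <= cys_pos <= params.lipobox_c_max and h_end < cys_pos:
            return m.start() + 1
    return None


def detect_lpxtg_anchor(
    record: ProteinRecord,
    params: ClassifierParams = ClassifierParams(),
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> Optional[int]:
    """1-based position of the LPXTG leucine, or ``None``.

    Requires the motif to start within the final ``lpxtg_c_window`` residues,
    a transmembrane window (width ``tm_window``, mean KD >= ``h_thresh``)
    strictly after the motif, and >= ``tail_min_kr`` K/R residues in the final
    ``tail_len``. Among candidate motifs the most C-terminal one with a
    qualifying TM window downstream is reported.
    """
    seq = record.sequence
    if len(seq) < params.lpxtg_c_window:
        return None
    tail = seq[-params.tail_len :]
    if tail.count("K") + tail.count("R") < params.tail_min_kr:
        return None
    search_from = len(seq) - params.lpxtg_c_window  # 0-based earliest motif start
    matches = [m for m in _LPXTG_RE.finditer(seq) if m.start() >= search_from]
    if not matches:
        return None
    means = sliding_window_means(seq, params.tm_window, scale)
    for m in reversed(matches):
        motif_end = m.start() + 5  # 0-based index just past the motif
        region = means[motif_end:] if motif_end < len(means) else np.empty(0)
        if region.size and np.nanmax(region) >= params.h_thresh:
            return m.start() + 1
    return None


def classify_protein(
    record: ProteinRecord,
    params: ClassifierParams = ClassifierParams(),
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> SurfaceCall:
    """Run all three detectors and assign one category by precedence."""
    sp = detect_signal_peptide(record, params, scale)
    lipobox = detect_lipobox(record, sp, params, scale)
    lpxtg = detect_lpxtg_anchor(record, params, scale)
    if lpxtg is not None:
        category = "lpxtg_anchored"
    elif lipobox is not None:
        category = "lipoprotein"
    elif sp is not None:
        category = "secreted"
    else:
        category = "none"
    return SurfaceCall(
        protein_id=record.id,
        category=category,
        signal_peptide=sp,
        lipobox_pos=lipobox,
        lpxtg_pos=lpxtg,
    )


@dataclass(frozen=True)
class ProteomeSummary:
    n_total: int
    n_surface: int
    n_secreted: int
    n_lipoprotein: int
    n_lpxtg: int

    def to_dict(self) -> dict:
        return asdict(self)


def classify_proteome(
    proteome: Proteome,
    params: ClassifierParams = ClassifierParams(),
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> tuple[list[SurfaceCall], ProteomeSummary]:
    """Classify every protein; returns the calls plus category counts."""
    calls = [classify_protein(rec, params, scale) for rec in proteome]
    n_sec = sum(c.category == "secreted" for c in calls)
    n_lipo = sum(c.category == "lipoprotein" for c in calls)
    n_lpxtg = sum(c.category == "lpxtg_anchored" for c in calls)
    summary = ProteomeSummary(
        n_total=len(calls),
        n_surface=n_sec + n_lipo + n_lpxtg,
        n_secreted=n_sec,
        n_lipoprotein=n_lipo,
        n_lpxtg=n_lpxtg,
    )
    return calls, summary


def calls_to_rows(calls: Iterable[SurfaceCall]) -> list[dict]:
    """Flatten calls into TSV-ready rows."""
    rows = []
    for c in calls:
        sp = c.signal_peptide
        rows.append(
            {
                "protein_id": c.protein_id,
                "category": c.category,
                "cleavage_pos": sp.cleavage_pos if sp else "",
                "sp_mean_kd": round(sp.sp_mean_kd, 6) if sp else "",
                "lipobox_pos": c.lipobox_pos if c.lipobox_pos is not None else "",
                "lpxtg_pos": c.lpxtg_pos if c.lpxtg_pos is not None else "",
            }
        )
    return rows
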