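"""Benchmark harness for profiling a real annotated proteome.

The surface-hydropathy analysis was originally reported for the deposited
*Lactiplantibacillus plantarum* M2 proteome (GenBank JBQOUW000000000,
3226 proteins). The heuristic spans and thresholds behind that report are
unpublished, so agreement with the reference statistics below depends on
classifier-parameter tuning; this module records the reference values and
runs the full pipeline on any protein FASTA so a locally supplied proteome
can be compared against them. The package never downloads the accession.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from probiosurf.group_stats import build_gravy_records, summarize, surface_profile_report
from probiosurf.proteome_io import read_fasta
from probiosurf.surface_classifier import ClassifierParams, classify_proteome

#: Reference statistics reported for the M2 proteome (for comparison only;
#: never used in any computation).
M2_REFERENCE = {
    "n_proteins": 3226,
    "n_surface": 199,
    "n_secreted": 196,
    "n_lipoprotein": 1,
    "n_lpxtg": 2,
    "proteome_median_gravy": -0.1828,
    "surface_median_gravy": -0.2148,
    "surface_frac_negative_pct": 84.9,
    "background_frac_negative_pct": 69.4,
    "secreted_mature_median_gravy": -0.2466,
    "secreted_full_median_gravy": -0.2171,
}


@dataclass
class BenchmarkReport:
    summary: dict
    proteome_median_gravy: float
    surface_median_gravy: float
    surface_frac_negative_pct: float
    secreted_mature_median_gravy: Optional[float]
    reference: dict

    def deltas(self) -> dict[str, float]:
        """Observed minus reference, for the overlapping keys."""
        observed = {
            "proteome_median_gravy": self.proteome_median_gravy,
            "surface_median_gravy": self.surface_median_gravy,
            "surface_frac_negative_pct": self.surface_frac_negative_pct,
            "secreted_mature_median_gravy": self.secreted_mature_median_gravy,
        }
        return {
            key: observed[key] - self.reference[key]
            for key in observed
            if observed[key] is not None
        }


def run_benchmark(
    fasta_path: str | Path,
    params: ClassifierParams = ClassifierParams(),
) -> BenchmarkReport:
    """Profile a protein FASTA and report the benchmark statistics."""
    proteome = read_fasta(fasta_path)
    calls, summary = classify_proteome(proteome, params)
    records = build_gravy_records(proteome, calls)
    full = [r.gravy_full for r in records]
    surface = [r.gravy_full for r in records if r.category != "none"]
    mature = [
        r.gravy_mature
        for r in records
        if r.category == "secreted" and r.gravy_mature is not None
    ]
    surface_summary = summarize(surface) if surface else None
    return BenchmarkReport(
        summary=summary.to_dict(),
        proteome_median_gravy=summarize(full).median,
        surface_median_gravy=surface_summary.median if surface_summary else float("nan"),
        surface_frac_negative_pct=(
            100.0 * surface_summary.frac_negative if surface_summary else float("nan")
        ),
        secreted_mature_median_gravy=summarize(mature).median if mature else None,
        reference=dict(M2_REFERENCE),
    )
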