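"""Group comparison of GRAVY distributions: summaries, Welch's t, Mann-Whitney U.

Quartiles use the linear-interpolation convention (numpy's default), the
fraction-negative statistic uses strict ``< 0``, and all tests are two-sided.
The Mann-Whitney p-value is exact (full enumeration of rank assignments) for
tie-free samples with ``min(n) <= 8``, otherwise the normal approximation with
tie and continuity corrections is used.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from probiosurf.hydropathy import gravy, gravy_mature


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    frac_negative: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupComparison:
    label: str
    summary_x: GroupSummary
    summary_y: GroupSummary
    welch_t: float
    welch_df: float
    welch_p: float
    mwu_u: float
    mwu_p: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["summary_x"] = self.summary_x.to_dict()
        d["summary_y"] = self.summary_y.to_dict()
        return d


def summarize(values: Sequence[float]) -> GroupSummary:
    """Five-number-style summary; quartiles by linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        frac_negative=float((arr < 0).mean()),
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Welch's t-test with Welch-Satterthwaite degrees of freedom.

    Degenerate case: both sample variances zero with equal means gives
    ``t = 0, p = 1`` by convention (zero variance, zero difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t-test requires n >= 2 in both groups")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(x.size + y.size - 2)
        if x.mean() == y.mean():
            return {"t": 0.0, "df": df, "p": 1.0}
        return {"t": float(np.sign(x.mean() - y.mean()) * np.inf), "df": df, "p": 0.0}
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when ``min(n_x, n_y) <= 8`` and the pooled sample
    is tie-free; otherwise the normal approximation with tie correction and
    continuity correction. ``U`` is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney U requires nonempty groups")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def compare_groups(x: Sequence[float], y: Sequence[float], label: str) -> GroupComparison:
    """Both tests plus summaries for two value collections."""
    welch = welch_t_test(x, y)
    mwu = mann_whitney_u(x, y)
    return GroupComparison(
        label=label,
        summary_x=summarize(x),
        summary_y=summarize(y),
        welch_t=welch["t"],
        welch_df=welch["df"],
        welch_p=welch["p"],
        mwu_u=mwu["U"],
        mwu_p=mwu["p"],
    )


@dataclass(frozen=True)
class GravyRecord:
    """Per-protein GRAVY row: full-chain value, mature value when cleaved."""

    protein_id: str
    gravy_full: float
    category: str
    gravy_mature: Optional[float] = None
    n_scored_residues: int = 0

    def __post_init__(self) -> None:
        if not -4.5 <= self.gravy_full <= 4.5:
            raise ValueError(f"{self.protein_id}: GRAVY {self.gravy_full} outside [-4.5, 4.5]")

    def to_dict(self) -> dict:
        return asdict(self)


def build_gravy_records(proteome, calls) -> list[GravyRecord]:
    """Join a proteome with its surface calls into GRAVY rows.

    Mature GRAVY is computed only for proteins with a signal-peptide call
    (secreted proteins always have one; lipoproteins may, as a by-product of
    the shared hydrophobic-region criterion).
    """
    by_id = {c.protein_id: c for c in calls}
    records = []
    for rec in proteome:
        call = by_id[rec.id]
        mature = None
        if call.signal_peptide is not None:
            mature = gravy_mature(rec.sequence, call.signal_peptide.cleavage_pos)
        records.append(
            GravyRecord(
                protein_id=rec.id,
                gravy_full=gravy(rec.sequence),
                gravy_mature=mature,
                category=call.category,
                n_scored_residues=sum(rec.sequence.count(a) for a in "ACDEFGHIKLMNPQRSTVWY"),
            )
        )
    return records


def surface_profile_report(gravy_records: Sequence[GravyRecord]) -> dict[str, GroupComparison]:
    """The three comparisons of the surface-hydropathy analysis.

    (a) surface subset vs whole proteome, (b) surface subset vs non-surface
    background, (c) for secreted proteins, mature-chain GRAVY vs full-chain
    GRAVY (two summaries over the same proteins; no paired test is claimed).
    """
    full = [r.gravy_full for r in gravy_records]
    surface = [r.gravy_full for r in gravy_records if r.category != "none"]
    background = [r.gravy_full for r in gravy_records if r.category == "none"]
    secreted_full = [r.gravy_full for r in gravy_records if r.category == "secreted"]
    secreted_mature = [
        r.gravy_mature for r in gravy_records
        if r.category == "secreted" and r.gravy_mature is not None
    ]
    for name, grp in (("surface", surface), ("non-surface", background),
                      ("secreted", secreted_full)):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 proteins")
    return {
        "surface_vs_proteome": compare_groups(surface, full, "surface vs whole proteome"),
        "surface_vs_background": compare_groups(surface, background, "surface vs non-surface"),
        "secreted_mature_vs_full": compare_groups(
            secreted_mature, secreted_full, "secreted mature vs full GRAVY"
        ),
    }
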