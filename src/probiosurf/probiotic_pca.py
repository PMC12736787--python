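"""Stress-tolerance PCA: log-CFU panels -> retention fractions -> Z-scores -> biplot.

Each isolate's survival under acid, bile and lysozyme stress is summarized as
a retention fraction ``10 ** (log10 CFU_final - log10 CFU_initial)`` — the
surviving fraction of viable cells — and combined with the mean antagonism
halo diameter (mm) into a four-variable feature matrix. Columns are
standardized with population-SD Z-scores (the common PCA-preprocessing
default; switchable) and decomposed by PCA with a deterministic sign
convention: each loading column's largest-magnitude entry is made positive,
since biplot orientation is otherwise arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

STRESSORS = ("acid", "bile", "lysozyme")
FEATURE_COLUMNS = ("antagonism", "acid_retention", "bile_retention", "lysozyme_retention")

# singular values below this (relative to the largest) count as rank-deficient zeros
_ZERO_RATIO = 1e-12


@dataclass(frozen=True)
class StressPanel:
    """Per-isolate stress-survival endpoints and antagonism halo."""

    isolate_id: str
    log_cfu_initial: Mapping[str, float]  # log10 CFU/mL at exposure start, per stressor
    log_cfu_final: Mapping[str, float]    # log10 CFU/mL at exposure end, per stressor
    antagonism_mm: float                  # mean inhibition-halo diameter

    def __post_init__(self) -> None:
        if self.antagonism_mm < 0:
            raise ValueError(f"{self.isolate_id}: antagonism halo must be >= 0")
        for name, mapping in (("initial", self.log_cfu_initial), ("final", self.log_cfu_final)):
            for stressor, value in mapping.items():
                if not np.isfinite(value):
                    raise ValueError(f"{self.isolate_id}: non-finite {name} log CFU for {stressor}")


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame                 # isolates x components
    loadings: pd.DataFrame               # variables x components
    explained_variance_ratio: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "scores": {idx: row.tolist() for idx, row in self.scores.iterrows()},
            "loadings": {idx: row.tolist() for idx, row in self.loadings.iterrows()},
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "components": list(self.scores.columns),
        }


def retention_fraction(log_initial: float, log_final: float) -> float:
    """Surviving fraction ``10 ** (log_final - log_initial)`` = N_final/N_initial."""
    if not (np.isfinite(log_initial) and np.isfinite(log_final)):
        raise ValueError("log CFU endpoints must be finite")
    return float(10.0 ** (log_final - log_initial))


def build_feature_matrix(panels: Sequence[StressPanel]) -> pd.DataFrame:
    """One row per isolate, fixed column order: halo then the three retentions."""
    if len(panels) < 2:
        raise ValueError("need at least 2 isolates")
    rows = {}
    for panel in panels:
        values = [panel.antagonism_mm]
        for stressor in STRESSORS:
            if stressor not in panel.log_cfu_initial or stressor not in panel.log_cfu_final:
                raise ValueError(f"isolate {panel.isolate_id}: {stressor}")
            values.append(
                retention_fraction(panel.log_cfu_initial[stressor], panel.log_cfu_final[stressor])
            )
        rows[panel.isolate_id] = values
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))


def zscore_columns(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column-wise Z-scores; population SD (``ddof=0``) by default."""
    sd = matrix.std(ddof=ddof, axis=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) {constant}: standardization undefined")
    return (matrix - matrix.mean(axis=0)) / sd


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of a standardized feature matrix with deterministic orientation.

    Components come from the SVD of the column-centered matrix; ratios below
    1e-12 of the total variance are reported as exactly 0 (with 3 isolates the
    trailing components are numerically null).
    """
    x = matrix.to_numpy(dtype=float)
    n_comp = min(x.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # variables x components, orthonormal columns
    ratios = model.explained_variance_ratio_.copy()
    ratios[ratios < _ZERO_RATIO] = 0.0
    if not np.any(ratios > 0):
        raise ValueError("matrix has rank 0: no principal components")
    # orientation: largest-|loading| entry of each component made positive
    for k in range(n_comp):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=ratios,
    )


def read_panel_tsv(path) -> list[StressPanel]:
    """Read stress panels from long-format TSV.

    Columns: isolate, stressor (or ``antagonism``), log_cfu_initial,
    log_cfu_final, antagonism_mm. The halo may be given on any row of its
    isolate; it must be consistent when repeated.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"isolate", "stressor", "log_cfu_initial", "log_cfu_final", "antagonism_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel TSV missing columns {sorted(missing)}")
    panels = []
    for isolate, grp in df.groupby("isolate", sort=False):
        initial, final = {}, {}
        for _, row in grp.iterrows():
            initial[row["stressor"]] = float(row["log_cfu_initial"])
            final[row["stressor"]] = float(row["log_cfu_final"])
        halos = grp["antagonism_mm"].dropna().unique()
        if len(halos) != 1:
            raise ValueError(f"isolate {isolate}: inconsistent antagonism_mm")
        panels.append(
            StressPanel(
                isolate_id=str(isolate),
                log_cfu_initial=initial,
                log_cfu_final=final,
                antagonism_mm=float(halos[0]),
            )
        )
    return panels


def run_pca_pipeline(panels: Sequence[StressPanel]) -> PCAResult:
    """Panels -> feature matrix -> Z-scores -> PCA, in one call."""
    return pca(zscore_columns(build_feature_matrix(panels)))
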