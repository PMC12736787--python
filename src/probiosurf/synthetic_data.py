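"""Seeded generators for proteomes, assay plates and stress panels.

The proteome generator emulates the statistical structure the surface-
hydropathy analysis assumes: ~3,000 proteins of which ~6% carry planted
surface-localization constructs (secreted >> lipoprotein ~ LPXTG), a
background GRAVY distribution centered near -0.18, and a surface subset
whose full-chain GRAVY is shifted toward more negative values by a
configurable effect size. Residue composition is tuned by mixing a
hydrophilic and a hydrophobic composition with a weight solved by
bisection so the expected Kyte-Doolittle mean hits the target exactly (the
map weight -> expected mean is linear, hence monotone); for surface
proteins the random-region target is solved per protein so the whole-chain
expectation lands on background + shift despite the hydrophobic planted
construct.

Planted constructs are built to the classifier's documented definitions at
the supplied params and validated at generation time: a planted protein
whose target detector fails raises ``RuntimeError`` (a generator bug), while
a planted protein accidentally matching a higher-precedence motif in its
random region is discarded and redrawn, so the truth labels always agree
with the classifier's category precedence.

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from probiosurf.assay_metrics import BIOFILM_CLASSES, PlateReadings, classify_od_ratio
from probiosurf.hydropathy import _KD_VALUES
from probiosurf.probiotic_pca import STRESSORS, StressPanel
from probiosurf.proteome_io import ProteinRecord, Proteome
from probiosurf.surface_classifier import (
    ClassifierParams,
    classify_protein,
    detect_lipobox,
    detect_lpxtg_anchor,
    detect_signal_peptide,
)

# hydrophilic / hydrophobic pole compositions for the bisection mix;
# their union covers all 20 canonical residues
_PHILIC = tuple("DEKRNQSTGHP")
_PHOBIC = tuple("ACFILMVWY")

# alphabets for planted constructs, chosen to avoid accidental motif letters
_POLAR_NO_AC = tuple("DEGHKNPQRST")       # prefix/linker: no A (A-X-A), no C (lipobox)
_HYDROPHOBIC_CORE = tuple("LIVF")          # h-region / TM: KD >= 2.8, no A/C/P


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Study conditions for a synthetic proteome."""

    n_proteins: int = 3000
    frac_secreted: float = 0.060
    frac_lipoprotein: float = 0.0005
    frac_lpxtg: float = 0.001
    length_mean: float = 300.0
    length_sd: float = 120.0
    background_gravy_target: float = -0.18
    surface_gravy_shift: float = -0.03
    seed: int = 0
    params: ClassifierParams = field(default_factory=ClassifierParams)

    def __post_init__(self) -> None:
        fracs = (self.frac_secreted, self.frac_lipoprotein, self.frac_lpxtg)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("surface fractions must lie in [0, 1] and sum to < 1")
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be >= 10")


@dataclass(frozen=True)
class PlantedTruth:
    category: str
    cleavage_pos: Optional[int] = None
    lipobox_pos: Optional[int] = None
    lpxtg_pos: Optional[int] = None


@dataclass
class LabeledProteome:
    proteome: Proteome
    truth: dict[str, PlantedTruth]


def tune_composition(target: float, tol: float = 1e-12) -> tuple[tuple[str, ...], np.ndarray]:
    """Residue alphabet and probabilities with expected KD mean == ``target``.

    Mixes uniform hydrophilic and hydrophobic pole compositions; the mixing
    weight is solved by bisection on the (linear, increasing) expected mean.
    """
    if not -4.5 < target < 4.5:
        raise ValueError(f"GRAVY target {target} outside the Kyte-Doolittle range")
    alphabet = _PHILIC + _PHOBIC
    p_phil = np.array([1.0 / len(_PHILIC)] * len(_PHILIC) + [0.0] * len(_PHOBIC))
    p_phob = np.array([0.0] * len(_PHILIC) + [1.0 / len(_PHOBIC)] * len(_PHOBIC))
    kd = np.array([_KD_VALUES[a] for a in alphabet])

    def expected(w: float) -> float:
        return float(((1 - w) * p_phil + w * p_phob) @ kd)

    lo, hi = 0.0, 1.0
    if not expected(lo) <= target <= expected(hi):
        raise ValueError(f"GRAVY target {target} infeasible for the pole compositions")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    w = (lo + hi) / 2
    return alphabet, (1 - w) * p_phil + w * p_phob


def _draw_seq(rng: np.random.Generator, n: int, alphabet: Sequence[str], probs: np.ndarray) -> str:
    return "".join(rng.choice(alphabet, size=n, p=probs)) if n > 0 else ""


def _count(frac: float, n: int) -> int:
    return int(np.floor(frac * n + 0.5))


def _kd_sum(seq: str) -> float:
    return sum(_KD_VALUES[a] for a in seq)


def _compensated_draw(rng, n: int, full_target: float, construct_sum: float, total: int) -> str:
    """Random region whose composition makes the whole-protein expected GRAVY hit target.

    Solves the per-protein mean the random region must have to offset the
    realized planted construct, then tunes a composition to it by bisection.
    """
    region_target = (full_target * total - construct_sum) / n
    alphabet, probs = tune_composition(region_target)
    return _draw_seq(rng, n, alphabet, probs)


def _plant_secreted(rng, length, params, full_target) -> tuple[str, PlantedTruth]:
    """N-terminal hydrophobic core + A-X-A cleavage site + compensated mature chain."""
    h = int(rng.integers(params.h_window, params.h_window + 5))
    c_lo = max(params.sp_cleave_min, h + 4)  # prefix >= 1
    c_hi = max(c_lo, min(params.sp_cleave_max, length // 2))
    c = int(rng.integers(c_lo, c_hi + 1))
    prefix_len = c - 3 - h
    prefix = "M" + _draw_seq(rng, prefix_len - 1, _POLAR_NO_AC, None)
    core = _draw_seq(rng, h, _HYDROPHOBIC_CORE, None)
    site = "A" + str(rng.choice(list(_POLAR_NO_AC))) + "A"
    construct = prefix + core + site
    mature_len = max(length - c, 20)
    mature = _compensated_draw(rng, mature_len, full_target, _kd_sum(construct), c + mature_len)
    return construct + mature, PlantedTruth("secreted", cleavage_pos=c)


def _plant_lipoprotein(rng, length, params, full_target) -> tuple[str, PlantedTruth]:
    """Hydrophobic core + lipobox L[AS][AG]C with the Cys in the legal span."""
    h = int(rng.integers(params.h_window, params.h_window + 5))
    c_lo = max(params.lipobox_c_min, h + 6)  # prefix >= 1, Cys at position c
    c_hi = max(c_lo, min(params.lipobox_c_max, length // 2))
    c = int(rng.integers(c_lo, c_hi + 1))
    prefix_len = c - 4 - h
    prefix = "M" + _draw_seq(rng, prefix_len - 1, _POLAR_NO_AC, None)
    core = _draw_seq(rng, h, _HYDROPHOBIC_CORE, None)
    lipobox = "L" + str(rng.choice(["A", "S"])) + str(rng.choice(["A", "G"])) + "C"
    construct = prefix + core + lipobox
    mature_len = max(length - c, 20)
    mature = _compensated_draw(rng, mature_len, full_target, _kd_sum(construct), c + mature_len)
    return construct + mature, PlantedTruth("lipoprotein", lipobox_pos=c - 3)


def _plant_lpxtg(rng, length, params, full_target) -> tuple[str, PlantedTruth]:
    """Body + LPXTG + transmembrane stretch + K/R-rich tail at the C-terminus."""
    spacer_len = int(rng.integers(0, max(1, params.lpxtg_c_window - params.tm_window - params.tail_len - 5 + 1)))
    motif = "LP" + str(rng.choice(list(_POLAR_NO_AC))) + "TG"
    spacer = _draw_seq(rng, spacer_len, _POLAR_NO_AC, None)
    tm = _draw_seq(rng, params.tm_window, _HYDROPHOBIC_CORE, None)
    n_kr = int(rng.integers(params.tail_min_kr, params.tail_len + 1))
    tail_letters = list(rng.choice(["K", "R"], size=n_kr)) + list(
        rng.choice(["D", "E", "N", "Q", "S", "T"], size=params.tail_len - n_kr)
    )
    rng.shuffle(tail_letters)
    construct = motif + spacer + tm + "".join(str(a) for a in tail_letters)
    body_len = max(length - len(construct), 30)
    body = "M" + _compensated_draw(
        rng, body_len - 1, full_target, _kd_sum(construct) + _KD_VALUES["M"],
        body_len + len(construct),
    )
    return body + construct, PlantedTruth("lpxtg_anchored", lpxtg_pos=body_len + 1)


_PLANTERS = {
    "secreted": _plant_secreted,
    "lipoprotein": _plant_lipoprotein,
    "lpxtg_anchored": _plant_lpxtg,
}


def generate_proteome(spec: SyntheticProteomeSpec) -> LabeledProteome:
    """Generate a labeled synthetic proteome, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    params = spec.params
    bg_alphabet, bg_probs = tune_composition(spec.background_gravy_target)
    surface_target = spec.background_gravy_target + spec.surface_gravy_shift
    n = spec.n_proteins
    counts = {
        "secreted": _count(spec.frac_secreted, n),
        "lipoprotein": _count(spec.frac_lipoprotein, n),
        "lpxtg_anchored": _count(spec.frac_lpxtg, n),
    }
    n_background = n - sum(counts.values())

    lengths = rng.normal(spec.length_mean, spec.length_sd, size=n)
    lengths = np.maximum(lengths, 60).astype(int)

    records: list[ProteinRecord] = []
    truth: dict[str, PlantedTruth] = {}
    idx = 0
    for category, n_cat in counts.items():
        planter = _PLANTERS[category]
        for _ in range(n_cat):
            pid = f"syn{idx + 1:05d}"
            for _attempt in range(50):
                seq, planted = planter(rng, int(lengths[idx]), params, surface_target)
                rec = ProteinRecord(id=pid, sequence=seq, description=f"planted:{category}")
                _validate_planted(rec, planted, params)
                if classify_protein(rec, params).category == category:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"could not plant a clean {category} sequence for {pid}")
            records.append(rec)
            truth[pid] = planted
            idx += 1
    for _ in range(n_background):
        pid = f"syn{idx + 1:05d}"
        seq = _draw_seq(rng, int(lengths[idx]), bg_alphabet, bg_probs)
        records.append(ProteinRecord(id=pid, sequence=seq, description="background"))
        truth[pid] = PlantedTruth("none")
        idx += 1
    proteome = Proteome(records=records, source_label=f"synthetic(seed={spec.seed})")
    return LabeledProteome(proteome=proteome, truth=truth)


def _validate_planted(rec: ProteinRecord, planted: PlantedTruth, params: ClassifierParams) -> None:
    """Planted constructs must pass their target detector — else the generator is broken."""
    if planted.category == "secreted":
        call = detect_signal_peptide(rec, params)
        if call is None or call.cleavage_pos != planted.cleavage_pos:
            raise RuntimeError(f"{rec.id}: planted signal peptide not detected as planted")
    elif planted.category == "lipoprotein":
        if detect_lipobox(rec, None, params) != planted.lipobox_pos:
            raise RuntimeError(f"{rec.id}: planted lipobox not detected as planted")
    elif planted.category == "lpxtg_anchored":
        if detect_lpxtg_anchor(rec, params) != planted.lpxtg_pos:
            raise RuntimeError(f"{rec.id}: planted LPXTG anchor not detected as planted")


# --- assay plates -----------------------------------------------------------

_CLASS_MULTIPLIER = {"Negative": 1.0, "Weak": 1.5, "Moderate": 3.0, "Strong": 5.0}
_BOUNDARY_MULTS = (1.0, 2.0, 4.0)
_Z_99 = 2.5758293035489004  # norm.ppf(0.995): two-sided 99% preservation


def generate_plate(
    true_class: str,
    odc_mean: float = 0.08,
    noise_sd: float = 0.001,
    n_replicates: int = 4,
    seed: int = 0,
) -> PlateReadings:
    """Replicate OD630 readings around class-consistent means.

    The test-well mean is a class multiplier of the control mean (Weak 1.5x,
    Moderate 3x, Strong 5x; Negative 1.0x, i.e. exactly on its boundary).
    ``noise_sd`` must keep the class preserved with probability > 0.99, which
    for the boundary-sitting Negative class admits only ``noise_sd = 0``.
    """
    if true_class not in BIOFILM_CLASSES:
        raise ValueError(f"unknown biofilm class {true_class!r}")
    if odc_mean <= 0:
        raise ValueError("odc_mean must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mult = _CLASS_MULTIPLIER[true_class]
    if noise_sd > 0:
        dist = min(abs(mult - b) for b in _BOUNDARY_MULTS) * odc_mean
        se = noise_sd * np.sqrt((1.0 + mult**2) / n_replicates)
        if dist <= _Z_99 * se:
            raise ValueError(
                f"noise_sd {noise_sd} too large to preserve class {true_class} "
                f"with probability > 0.99 at odc_mean {odc_mean}"
            )
    rng = np.random.default_rng(seed)
    odc = np.maximum(odc_mean + rng.normal(0.0, noise_sd, n_replicates), 0.0)
    odt = np.maximum(mult * odc_mean + rng.normal(0.0, noise_sd, n_replicates), 0.0)
    readings = PlateReadings(od_test=tuple(odt), od_control=tuple(odc), wavelength_nm=630)
    if noise_sd > 0:
        realized = classify_od_ratio(float(odt.mean()), float(odc.mean()))
        if realized != true_class:  # pragma: no cover - < 1% by construction
            raise RuntimeError(f"noise flipped plate class {true_class} -> {realized}")
    return readings


# --- stress panels ----------------------------------------------------------


def generate_stress_panel(
    n_isolates: int = 3,
    effect_profile: Optional[dict] = None,
    seed: int = 0,
) -> list[StressPanel]:
    """Seeded log-CFU endpoints and antagonism halos for ``n_isolates`` isolates.

    ``effect_profile`` keys (all optional): ``dominant`` — isolate id given
    the best value in all four variables; ``advantage`` — margin added to the
    best competitor (log10 units for retentions, scaled to mm for halos,
    default 0.5); ``noise_sd`` — SD of the per-stressor delta-log noise
    (default 0.3; 0 makes all isolates identical, a degenerate panel with
    constant columns).
    """
    if n_isolates < 2:
        raise ValueError("need at least 2 isolates")
    profile = dict(effect_profile or {})
    dominant = profile.get("dominant")
    advantage = float(profile.get("advantage", 0.5))
    noise_sd = float(profile.get("noise_sd", 0.3))
    rng = np.random.default_rng(seed)
    ids = [f"M{i + 1}" for i in range(n_isolates)]
    if dominant is not None and dominant not in ids:
        raise ValueError(f"dominant isolate {dominant!r} not among {ids}")
    base_delta = {"acid": -1.5, "bile": -1.0, "lysozyme": -0.8}  # log10 drops
    panels: dict[str, StressPanel] = {}
    deltas: dict[str, dict[str, float]] = {}
    halos: dict[str, float] = {}
    for iso in ids:
        deltas[iso] = {
            s: base_delta[s] + rng.normal(0.0, noise_sd) for s in STRESSORS
        }
        halos[iso] = max(8.0 + rng.normal(0.0, 4.0 * noise_sd), 0.0)
    if dominant is not None:
        others = [i for i in ids if i != dominant]
        for s in STRESSORS:
            deltas[dominant][s] = max(deltas[i][s] for i in others) + advantage
        halos[dominant] = max(halos[i] for i in others) + 4.0 * advantage
    for iso in ids:
        initial = {s: 8.0 for s in STRESSORS}
        final = {s: initial[s] + deltas[iso][s] for s in STRESSORS}
        panels[iso] = StressPanel(
            isolate_id=iso,
            log_cfu_initial=initial,
            log_cfu_final=final,
            antagonism_mm=halos[iso],
        )
    return [panels[i] for i in ids]
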