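# Methods

## Hydropathy

GRAVY is the arithmetic mean of Kyte–Doolittle per-residue hydropathy
values over a protein's canonical residues. The scale is the published
reference table (I = 4.5 … R = −4.5), immutable in the default
`KYTE_DOOLITTLE` object; alternative scales can be supplied but outputs are
labeled with the scale name.

Handling of non-canonical letters is a documented package choice: X, B, Z
and U are excluded from both numerator and denominator rather than scored
as 0. Scoring them 0 would drag X-rich draft annotations toward apparent
hydrophilicity; exclusion leaves the mean unbiased for the residues that
are actually known. The count of scored residues is carried alongside every
GRAVY value. A sequence with no canonical residue has no GRAVY and raises.

Two identities are exploited by the test suite and hold exactly in this
implementation: GRAVY of a concatenation is the length-weighted mean of
part GRAVYs, and the mature-chain GRAVY after cleaving a leader at position
c is below the full-chain GRAVY precisely when the leader's mean hydropathy
exceeds the full-chain mean.

## Surface classifier

The three detectors formalize the canonical sequence features of
Gram-positive surface proteins. All spans and thresholds live in
`ClassifierParams` (units: residues; hydropathy thresholds dimensionless):

| parameter | default | meaning |
|---|---|---|
| `sp_scan_len` | 45 | N-terminal span scanned for a hydrophobic window |
| `h_window` / `h_thresh` | 8 / 1.5 | hydrophobic-window width and mean-KD threshold |
| `sp_cleave_min/max` | 15 / 45 | allowed A-X-A cleavage positions |
| `lipobox_c_min/max` | 15 / 40 | allowed lipobox Cys positions |
| `lpxtg_c_window` | 50 | C-terminal span searched for LPXTG |
| `tm_window` | 15 | transmembrane-window width after the motif |
| `tail_len` / `tail_min_kr` | 10 / 2 | charged-tail span and minimum K/R count |

Defaults were chosen so that canonical Gram-positive signal peptides
(20–35 aa, hydrophobic core ≥ 8 residues) and sortase anchors (motif
roughly 30–40 residues from the C-terminus) are detectable; they are
deliberately config-exposed because the features themselves, not specific
numbers, define the biology.

Determinism and tie-breaking: the signal-peptide call uses the *first*
qualifying hydrophobic window and the *first* A-X-A whose second alanine
falls in `[max(sp_cleave_min, h_end+1), sp_cleave_max]` (the cleavage site
must lie strictly after the hydrophobic window); the LPXTG call uses the
*most C-terminal* motif occurrence that has a qualifying transmembrane
window strictly downstream, the tail condition being independent of the
motif position. The lipobox check requires only the hydrophobic region, not
a full cleavage-site call — lipoprotein signal peptides end in the lipobox
itself, so demanding an A-X-A would systematically miss them. An initial
Met is not required anywhere; annotated proteomes contain alternative
starts.

Categories are mutually exclusive with precedence
`lpxtg_anchored > lipoprotein > secreted`: anchored forms carry the most
specific evidence, and a lipobox is a more specific reading of an
N-terminal export signal than a generic cleavage site. All detector
evidence is retained on the call even when precedence overrides it.

## Group statistics

Summaries use numpy's linear-interpolation quartile convention, chosen and
documented because interquartile ranges are part of the reported output;
the fraction-negative statistic is strict (`< 0`). Both tests are
two-sided. Welch's t uses the Welch–Satterthwaite degrees of freedom (via
`scipy.stats.ttest_ind(equal_var=False)`); the fully degenerate case (both
variances zero, equal means) returns t = 0, p = 1 by convention. The
Mann–Whitney U is exact by full enumeration of the null distribution when
`min(n) ≤ 8` and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections
(`scipy.stats.mannwhitneyu`); the tests cross-check both regimes against an
independent enumeration oracle.

The profile report makes three comparisons: surface vs whole proteome,
surface vs non-surface background, and — for secreted proteins — mature
vs full GRAVY. The last is reported as two summaries with unpaired tests
attached for uniformity; no paired test is claimed, since the scientific
statement of interest is the shift of the medians. No multiple-testing
correction is applied across the three comparisons.

## Assay calculators

All four calculators are exact arithmetic on their inputs. Replicates are
averaged (arithmetic mean) before biofilm classification; standard
deviations are carried for reporting but never affect the class. Class
boundaries are inclusive on the upper side (ODt = 2·ODc is Weak,
ODt = 4·ODc is Moderate), making the classification scale-invariant in the
ODs. Negative aggregation/adhesion percentages are reported unclamped.

## Stress-tolerance PCA

Retention fractions `10^(Δlog CFU)` are the surviving-cell fractions; the
feature matrix is isolates × (antagonism halo, acid, bile, lysozyme
retention) in that fixed order. Z-scoring uses the population SD
(`ddof=0`), the common PCA-preprocessing default; it is switchable via the
`ddof` argument. Constant columns raise rather than silently producing
zeros.

PCA is the SVD of the centered standardized matrix
(`sklearn.decomposition.PCA`, full solver). Because biplot orientation is
arbitrary, a deterministic sign convention is applied: each loading
column's largest-magnitude entry is made positive, with scores flipped
accordingly. With 3 isolates at most 2 components carry variance; ratios
below 1e−12 of the total are reported as exactly 0. The test suite checks
orthonormal loadings, exact reconstruction (`scores · loadingsᵀ` equals the
centered matrix to 1e−9), and agreement of the variance ratios with a
direct numpy SVD.

## Synthetic data

The proteome generator emulates the data a surface-hydropathy analysis of
a LAB proteome sees: ~3,000 proteins, ~6% carrying surface features with
secreted ≫ lipoprotein ≈ LPXTG (defaults 6% / 0.05% / 0.1%), lengths
normal(300, 120) truncated at 60, a background GRAVY centered at −0.18 and
a surface subset shifted by a configurable effect (default −0.03).

Residue composition is tuned by mixing a uniform hydrophilic pole
(D,E,K,R,N,Q,S,T,G,H,P) with a uniform hydrophobic pole
(A,C,F,I,L,M,V,W,Y); the mixing weight is solved by bisection so the
expected per-residue KD mean hits the target (the map is linear and
monotone, so bisection converges to machine precision). For surface
proteins the random-region target is solved *per protein* so that the
whole-chain expected GRAVY lands on background + shift despite the
hydrophobic planted construct — the shift parameter therefore means what
the analysis measures: a displacement of the surface subset's full-chain
GRAVY distribution.

Planted constructs are built to the classifier's documented definitions
with positions randomized within the legal spans (cleavage sites across
[15, min(45, L/2)], lipobox Cys across [15, min(40, L/2)], LPXTG spacers
0–20 residues), and their prefix/core alphabets exclude the letters that
could create accidental earlier motif matches. Each planted sequence is
validated at generation time: if its target detector misses it, generation
fails loudly (that would be a generator bug); if its random region happens
to contain a higher-precedence motif, the sequence is redrawn from the same
seeded stream. Generators are pure functions of spec + seed.

What the generator does **not** emulate: real annotation noise
(pseudogenes, frameshifts, X-runs), genuine signal-peptide sequence
diversity (real h-regions are not drawn from {L,I,V,F}), correlated
composition along chains, or the functional-domain structure of real
surface proteins. Passing the recovery tests therefore shows the detectors
implement their stated definitions with high specificity on composition-
matched background — not that the heuristics reproduce any particular real
proteome's surface count, which is why profiling a real proteome is exposed
as a separate benchmark with tunable parameters
(`probiosurf.benchmark`; reference statistics recorded, FASTA supplied by
the user).

Plate generation places the test-well mean at a class multiplier of the
control mean (Weak 1.5×, Moderate 3×, Strong 5×, Negative 1×) and checks
feasibility: the requested noise must keep the realized class stable with
probability > 0.99, which the boundary-sitting Negative class satisfies
only at zero noise. Stress panels draw per-stressor log-drops around
(−1.5, −1.0, −0.8) for acid/bile/lysozyme with configurable noise; a
designated dominant isolate is set strictly best in all four variables by
a margin, which is the construction behind the dominant-isolate PCA
property.

## Problem sizes

The shipped verification runs use a 3,000-protein proteome for recovery
statistics, 100 seeded replicates for shift-detection power (200 surface vs
2,800 background, shift −0.05), 1,000 replicates at n = 30/30 for the null
calibration of both tests, and 3-isolate panels for the PCA geometry —
sizes chosen to match the study conditions the generator emulates while
keeping a full verification run around a minute on one CPU.

## Known limitations

* The heuristic classifier is intentionally simple; it has no positional
  weight matrices or HMMs, and its false-positive rate (~3–4% on
  composition-matched backgrounds) would differ on real proteomes.
* Exact reproduction of a published surface count for a real proteome
  depends on unpublished threshold choices; the benchmark module treats
  those as tunable and records the reference values for comparison only.
* The mature-vs-full comparison is deliberately unpaired (two summaries);
  a paired test would need a stated pairing model.
* `read_panel_tsv` expects complete panels; there is no imputation.
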