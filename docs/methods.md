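# Methods and design notes

## The model and its assumptions

The package analyzes a two-platform expression study of
hyperoxia-induced neonatal lung injury. The design is an incomplete
timepoint × treatment layout: room-air (RA) animals at P1, P14 and P29,
80%-O₂ animals at P14 and P29 only — no P1-O₂ cell can exist, because
exposure starts at birth. With 2 RA and 3 O₂ replicates per cell the
study has 12 samples in 5 cells.

Because the layout is incomplete, differential expression does not use
a full factorial decomposition. Each feature is fit with a **cell-means
model**: the five cell means, plus one residual variance pooled over
all cells (the df-weighted mean of within-cell sample variances) with
N − 5 = 7 residual degrees of freedom. The three biological questions
are pairwise contrasts inside that model — A: P29-RA vs P14-RA;
B: P14-O₂ vs P14-RA; C: P29-O₂ vs P29-RA — each tested as a two-sided
pooled-variance t. This is the "group comparison within a two-factor
ANOVA" that commercial array suites perform; an omnibus interaction F
is neither computable here (missing cell) nor what the contrasts ask.
Assumptions: Gaussian log2-scale noise, homoscedastic across cells
within a feature, independent features. Features with zero pooled
variance are flagged degenerate and excluded from p-value machinery
rather than given p = 0.

miRNA statistics run on **−ΔCT**, since a larger ΔCT means lower
expression; the sign convention then matches the mRNA side (positive =
up-regulated).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| CT ceiling | 35 | cycles | detectability limit; undetected reactions and CT > 35 are set here |
| copy-number slope | 3.34 | cycles per 10-fold | ideal PCR: 10^(1/3.34) ≈ 2 per cycle |
| per-cell divisor | 22 | — | closes the copies-per-cell formula under 30 pg RNA/cell |
| mRNA fold-change gate | 2 | linear ratio | reciprocal-negative convention, \|FC\| > 2 |
| miRNA fold-change gate | 4 | linear ratio | PCR platform is noisier per cycle; stricter gate |
| FDR level | 0.05 | — | Benjamini–Hochberg step-up, per contrast across features |
| low-expression floor | 5.0 | log2 units | probes whose max across samples stays below are dropped |
| detection fraction | 0.5 | — | miRNA detected if CT < 35 in ≥ half the samples of ≥ 1 cell |

The low-expression floor and the detection fraction are declared
conventions: the thresholds behind "low expression" and "detected" are
not derivable from the analysis itself, so both are exposed in the
pipeline configuration.

The **derived raw-p cutoff** (`bh_p_cutoff`) is the largest order
statistic p₍ᵢ₎ ≤ fdr·i/m. Selecting p ≤ cutoff is provably identical to
selecting BH q ≤ fdr; it is how an FDR criterion is reported as a plain
p threshold, and it is data-dependent — different inputs give different
cutoffs at the same FDR level.

## Pattern classification

Features significant in at least one contrast get exactly one label.
Hyperoxia membership takes precedence: B-and-C same sign → shared
patterns (mRNA 5/6; miRNA 5 for up), B-only (mRNA 3/4, miRNA 3/4),
C-only (mRNA 7/8, miRNA 6 for up); features significant only in A get
the developmental patterns (mRNA 1 = up, 2 = down; miRNA 1 = down,
2 = up — the two platforms' printed numberings differ and both are kept
as printed). B/C members with opposite signs, and miRNA combinations
outside the printed set (C-only down, shared down), go to an explicit
`discordant` bucket rather than being dropped, so pattern counts always
partition the significant union — an invariant the run report asserts.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *structure* the statistics rely on: the
incomplete design; log2-normal probe noise around baselines uniform on
[4, 12] log2 units (planted probes on [7, 11], so a default
low-expression filter cannot silently delete a plant); CT values built
from planted abundances at one cycle per 2-fold change around a U6
control, with a configurable fraction of assays forced above the
ceiling; group plants applied to the cells each contrast reads
(A shifts the whole P29 timepoint so B and C stay null; B shifts P14-O₂;
C shifts P29-O₂; shared B∩C plants shift both O₂ cells); repression
edges linking up-planted miRNAs to down-planted probes of the same
group; and prediction databases that drop true edges at a set miss rate
and add per-miRNA decoys.

It does **not** emulate: probe-level (pre-summarization) array
structure, intensity-dependent variance, correlated probes or
co-regulated gene modules, PCR efficiency differences between assays,
or sequence-based target prediction. Passing tests therefore
demonstrate that the *procedures* are correct and calibrated under
their stated assumptions — not that the thresholds are optimal for any
real dataset, where noise is heavier-tailed and features are
correlated.

Default generator conditions (the demo study): 2/3 replicates, 2000
probes with 50 planted per group + 25 shared B∩C, 521 miRNA assays with
8 per group + 20 shared, effect 2.5 log2 (≈5.7-fold, comfortably past
both gates), noise sd 0.25 log2, U6 at 20 cycles, 20% of assays forced
above the ceiling, 10 targets per up-miRNA, 30 decoys per miRNA, and
two databases at miss rates 0.2/0.35. Replicate noise is a free
parameter of the generator, not an estimate from any particular
dataset; 0.25 log2 units is a typical within-group array sd.

## Numerical choices

- Quantile normalization maps each column onto the mean of sorted
  columns; ties within a column receive the mean of the reference
  values at the tied ranks (deterministic, idempotent to 1e−12).
- BH adjustment is the standard step-up with a reverse cumulative
  minimum; q values are capped at 1 and order is preserved.
- Signed fold change: 2^d for d ≥ 0 else −2^(−d), so |FC| ≥ 1 and
  FC = +1 at no change.
- Hypergeometric p uses the survival function at overlap − 1
  (P(X ≥ k)); term ranking breaks ties by smaller p, then term id.
- The two-list spread is the population sd of the two −log₁₀ p values,
  |x − y|/2; any positive multiple gives the same ranking, the constant
  is recorded for reproducibility.
- Enrichment is reported at nominal p < 0.05 without multiple-testing
  correction, matching the tool convention this reporting style comes
  from; callers can BH-adjust the returned p column if preferred.
- ΔCT is computed after the ceiling is applied, so ceiling-valued
  miRNAs sit at a detectability floor rather than injecting
  pseudo-variation from the (35, 40) range.
- Stage seeds are spawned deterministically from the single top-level
  run seed.

## Design choices where the design was open

- **Per-contrast t vs omnibus F**: per-contrast tests were chosen
  because the three groups are the scientific questions and the layout
  lacks the cell a factorial F needs.
- **Same-group pairing**: candidate pairs require the miRNA rise and
  the mRNA fall in the *same* contrast group (B with B, C with C); the
  pooled alternative (any up-miRNA × any down-mRNA across B∪C) is
  obtainable by passing a single merged group, but same-group is the
  stricter, default reading of simultaneous anti-correlation.
- **Probe vs gene counting**: pairs are counted at probe level
  (collapsed over B/C duplicates), unique targets at gene level —
  many-probes-per-gene designs make these genuinely different numbers.
- **EASE-style adjusted scores** are not implemented; the plain
  hypergeometric tail is used.
- Efficiency from a standard curve is reported (with a 70–130%
  plausibility flag) but never used to correct 2^−ΔΔCT fold changes.

## Problem sizes used in validation

The shipped checks run at desk scale, chosen so the whole suite
finishes in a few minutes: null calibration at 2000 probes × 20 seeds,
pattern recovery at 1000 probes × 20 seeds, edge recall over 50 seeds,
enrichment detection over 100 runs, exhaustive hypergeometric
enumeration at universes ≤ 20, and the end-to-end demo at the default
generator conditions above. A real array (≈45k probe sets) is ~20×
larger per seed; all operations are vectorized across features and
scale linearly.

## Known limitations

- The pooled-variance t assumes homoscedastic cells; no moderated
  (shrinkage) variance estimator is provided, so very small effects at
  2 replicates are underpowered relative to limma-style analyses.
- Pattern labels are hard calls on thresholded significance; features
  hovering at the gates can flip patterns between nearby seeds.
- The copy-number formula inherits its ideal-efficiency assumption;
  absolute abundances for assays with poor efficiency are biased.
- GO terms are treated as flat, independent sets: no ontology-graph
  propagation, no term–term redundancy clustering.
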