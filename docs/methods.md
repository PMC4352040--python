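# Methods

## Screen model

A sensitized modifier screen measures each arrayed dsRNA amplicon under
two backgrounds — receptor knockdown (`Pvr`, sensitized) and a neutral
control (`GFP`) — in duplicate. Readings are luminescence counts
(ATP-content viability), strictly positive and approximately
log-normal. Standardization is per plate × condition × replicate
against that plate's control wells, which removes additive and
multiplicative plate effects exactly (the z score is invariant to
`reading -> a*reading + b` applied plate-wide, up to the sign of `a`).
Sigma uses the sample (n−1) estimator: control sets are small and the
same estimator then standardizes the controls to SD exactly 1. Whether
the original screen pooled controls across plates is not recoverable;
per-plate scoping is the package's declared choice and is standard for
arrayed screens.

Replicates are merged by averaging Z per background and recomputing
ZDiff from the merged means; when both backgrounds have equal replicate
counts this equals the mean of per-replicate ZDiff values. Amplicons
absent from one background are flagged incomplete and excluded from hit
calling.

### Hit classes

Thresholds are inclusive exactly as published: primary hits at
ZDiff ≥ 2 or ≤ −2; high confidence at ZDiffFinal ≥ 1.6 / ≤ −1.2.
The Suppressor/Upstream boundary was originally drawn by visual cluster
analysis and has no published numeric rule; the package declares
`z_control ≤ −2` (an upstream gene kills control-background cells on
its own) and also ships the clustering route for fidelity:
centered-correlation distance (1 − Pearson r of the centered
(Z[Pvr], Z[GFP], ZDiff) triple) with complete linkage.

One numerical caveat drove a design choice: after centering, the triple
has two degrees of freedom, so signature classes are directions on a
circle, and the suppressor and upstream directions are only ~30° apart
while the enhancer direction is antipodal. A flat 3-cluster cut of the
complete-linkage tree therefore frequently merges suppressors with
upstream genes while splitting another class along noise. The package
keeps the 3-cluster cut for display, but assigns classes by cutting the
same tree into 12 micro-clusters and mapping each micro-cluster
centroid through the signature rule; several micro-clusters may share a
class. On simulated screens this agrees with the explicit rule on
> 99% of hits (seeds 1–5) where the naive 3-cut agreed on as little as
45%.

### Error rates

`estimate_screen_error_rates` reproduces the audit arithmetic: FP =
(never-expressed genes that scored) / (never-expressed genes); FN =
(library amplicons of confirmed high-confidence genes that did not
score) / (all such amplicons). With the published counts — 1 of 355,
and 39 of 80 — it returns 0.28% and 48.75% (reported as <1% and 49%).

## Complex enrichment

The published analysis used a complex-enrichment service whose exact
internal statistic is not reproduced in the text beyond "1000 random
sets". The package scores a complex as the mean |ZDiffFinal| of its
members detected in the screen (members never screened are ignored;
strength is direction-agnostic) and draws same-size random gene sets
uniformly without replacement from the set of screened genes with a
defined score. The plus-one estimator keeps p ∈ [1/(N+1), 1] and valid
under the null. Raising any member's score can only raise the observed
mean at least as much as any random set's mean, so p is monotone
non-increasing in member scores under fixed draws. Each complex draws
from a child seed of the table-level seed, so results are independent
of table order.

## TMT quantification

Order of operations mirrors the narrative order of a standard TMT
phospho workflow: PSM filters → FDR → impurity correction → channel
normalization → replicate averaging → site collapsing.

* **Filters** are strict at the boundary ("greater than"): AScore > 13,
  isolation specificity > 0.75. AScore filtering acts per site on
  multiply-phosphorylated peptides; a peptide is dropped only when no
  site survives.
* **FDR.** Records are scanned in decreasing search-score order
  (decoys first at ties, the conservative direction) and the largest
  prefix with decoys/targets ≤ 1% is accepted; decoys are then removed.
* **Impurity correction** solves the full linear system
  `observed = M·true` rather than nearest-neighbor subtraction — exact
  for the stated mixing model and valid for any invertible non-negative
  leakage matrix; small negative solutions are clamped to zero. The
  matrix columns describe where each label's signal lands. TMT lot
  sheets are unpublished, so the matrix is an input;
  `default_impurity_matrix` provides a ±1-channel 3% leakage matrix.
* **Normalization** divides by channel totals and rescales by the mean
  total: all channel totals become equal while magnitudes stay
  comparable. Idempotent to machine precision.
* **Detectability** is `> 0` after impurity correction (no noise floor
  is published). A peptide detected in only one replicate label set is
  excluded wherever the design has replicates; the all-six-condition
  single-replicate layout passes through.
* **Site collapsing** sums per-condition intensities of all peptides
  covering a site before any ratio is computed; multiply-phosphorylated
  peptides contribute to each constituent site. Fold changes are
  reported at site level, since the downstream set logic counts
  phosphosites.

### Routing comparisons to runs

Reporter-ion ratios are only meaningful within one multiplexed run.
The study's layouts are: one replicated six-plex per Pvr background
(three conditions × two biological replicates each) and a third
six-plex spanning all six conditions once. `analyze_study` therefore
takes within-background comparisons (insulin response, EcR response)
from the replicated runs and cross-background comparisons (the
Pvr-dependent set, receptor-specific sets, k-means profiles) from the
all-six-condition run. Computing cross-background ratios across two
separate runs is not supported by the model: run-specific peptide
rosters make site-level sums incomparable, and in simulation this
inflates cross-run set sizes roughly two-fold.

### Set logic

"On average >1.5-fold" is realized as the ratio of replicate-averaged
normalized intensities (averaging precedes analysis in the source
workflow); the alternative — averaging per-replicate ratios — is
available as a configuration switch. Down-calls use the reciprocal
bound ratio < 1/1.5, symmetric on the log scale. The common Pvr/InR set
defaults to strict reciprocity (down upon Pvr loss AND up under insulin
in the low-Pvr background, plus the mirrored pairing); a
shared-directionality mode (same-direction insulin response in both
backgrounds) is provided because the source text supports either
reading. The k-means median normalization divides each site's linear
profile by its own median (the published text does not fix
subtract-vs-divide or linear-vs-log; divide-on-linear is the declared
default), with 25 restarts keeping the lowest within-cluster sum of
squares.

## Synthetic-data generator

The generator exists to make every stage testable with planted truth;
its defaults were declared once, before use, as a realistic study-scale
scenario.

**Screen.** 4 plates × 384 wells, 32 control wells in the last two
columns of each plate (dedicated control columns, as in arrayed-library
practice; the layout is recorded in the output so scoring never guesses),
duplicate measurement in both backgrounds, log-normal multiplicative
reading noise with CV 0.10 around a 50,000-count baseline. Planted
classes act multiplicatively: suppressors ×1.6 in the sensitized
background only, enhancers ×0.5 there, upstream genes ×0.5 in the
control background only — roughly ±5 control-SD signatures. Class
fractions default to 0.25/0.25/0.25/0.25, emulating a
verification-stage plate set strongly enriched for modifiers (a
genome-wide run would be almost entirely null); two amplicons per gene.
Under these conditions the pipeline recovers each class with ≥ 90%
sensitivity and precision (seeds 1–5); precision is bounded by the
null-amplicon tail crossing |ZDiff| = 2, which with ~32-well control-SD
estimation noise sits near 3–4% per side.

**Phospho.** 2000 phosphosites on ~670 proteins, 1 + Poisson(3)
peptides per site with log-normal (σ = 0.5) peptide abundances,
baseline site intensities log-normal around 10⁶. Planted fractions:
10% insulin-responsive, 10% Pvr-dependent, 5% common (reciprocal), 1%
EcR-responsive, at true fold 2.0; insulin- and EcR-responses are
planted half up / half down, as in the real data, which keeps channel
totals balanced so that summed-intensity normalization does not bias
ratios (planting one direction only introduces an ~10% systematic
ratio bias — a real property of total-intensity normalization worth
knowing about). Observed intensities are true intensities forward-mixed
through the impurity matrix with multiplicative log-normal noise
(CV 0.10 per PSM); per-replicate dropout (rate 0.05) zeroes the
affected replicate's observed channels — instrument-level missingness,
a peak absent from the 0.03 Da window reads as zero — so that the
"detectable iff > 0 after correction" rule behaves exactly (correcting
an observed zero with positive neighbors yields a negative, clamped
value). Decoy PSMs (10%) draw search scores from a null shifted ~5 SD
below targets, so a 1% FDR threshold exists. 5% of site assignments
carry sub-threshold AScores and 5% of PSMs sub-threshold isolation
specificity, exercising the filters.

What the generator does **not** emulate: plate-position (edge)
artifacts, raw spectra and chromatography, co-isolation interference
structure, protein-level abundance changes confounding phospho changes,
off-target amplicon effects, and correlated biological replicate noise.
Passing recovery tests therefore demonstrates correctness of the
scoring and set logic under the stated noise model, not robustness to
those real-data pathologies.

**Profile groups** for clustering benchmarks rejection-sample their
condition patterns until every pair is ≥ 1.5 apart in the
median-normalized space the clustering operates in, so the planted
groups are separable by construction.

## Numerical choices and degenerate inputs

* Z scoring requires ≥ 2 control wells and σ > 0; violations raise
  typed errors (`MissingControlsError`, `DegeneratePlateError`).
* Constant score triples (undefined correlation) are excluded from
  clustering and flagged.
* Fold calls require both condition values present and positive;
  everything else is `not_callable` and excluded from counts, so
  up + down + unchanged + not_callable always partitions the sites.
* Ties in the FDR scan count decoys before targets.
* The permutation p-value is never 0 by construction.
* All randomness flows through per-call seeded NumPy generators; the
  pipeline derives stage seeds from one root seed, and identical
  configuration reproduces every table byte-for-byte.

## Problem sizes

Tests and the acceptance script run the generators at their default
scale (4-plate screen, 2000-site phospho study, 1000–2000 random sets
for permutation checks), chosen as the package's standard demonstration
size; the full suite completes in well under a minute on one CPU.

## Known limitations

* The Suppressor/Upstream rule boundary (`z_control ≤ −2`) is a
  declared approximation of the original visual clustering.
* The complex-enrichment statistic is a transparent stand-in for the
  original service's unpublished internal score; p-values agree with
  exhaustive enumeration under this statistic, not necessarily with the
  original tool's output.
* Cross-run normalization (bridging channels, IRS) is out of scope;
  cross-background claims are supported only within the
  all-six-condition run.
* ZDiffFinal is computed for all genes with data, without gating on the
  verification-nomination cutoff (2.2), which the source text leaves
  unspecified.
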