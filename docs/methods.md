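# Methods

`exrnatools` implements a quantitative analysis pipeline for extracellular
RNA (exRNA) fractionated by sequential filtration into microvesicles (MV),
exosomes (EXO) and non-vesicular ribonucleoprotein particles (RNP), with
the donor cells (CELL) and fresh unconditioned media (FM) sequenced in
parallel as reference and blank. This note records the model behind each
stage, the tunable parameters with their defaults and rationale, what the
synthetic-data generator does and does not emulate, and the numerical
choices that make every result deterministic.

## Semi-absolute quantification

Counts are converted to femtomoles per microgram of total RNA using
exogenous spike-ins of known input amount (defaults: 1.25 fmol/ug dosed
into cellular samples, 5.0 fmol/ug into extracellular samples, one spike
species each). For each (culture, fraction, library) unit the pooled-ratio
estimator is used:

    scale [fmol/read] = sum_k known_fmol_k / sum_k reads_k

over the spikes with nonzero counts. The pooled ratio is the maximum-
likelihood estimate under multinomial counting and remains defined with a
single spike; with two or more spikes the through-origin fit quality
r^2 = (sum xy)^2 / (sum x^2 sum y^2) is reported as a diagnostic. A unit
whose spikes all have zero reads is flagged unquantifiable rather than
silently normalized. Cyclic-loess normalization of long libraries is a
deliberate non-feature: only the pooled-ratio estimator is implemented.

Units: 1 fmol/ug at the default per-EV RNA mass corresponds to about
2.7e-3 copies per EV (see Stoichiometry), which sets the natural scale of
the tables.

## Fresh-media blank correction

Fresh culture media contributes RNA that co-isolates with cell-derived
exRNA (of the order of 1-15% of the isolated mass, varying by fraction).
The correction is a per-fraction mass-weighted blank subtraction in
fmol/ug space:

    corrected = max(0, cm_fmol - m_f * fm_fmol)

where `m_f` is the measured ratio of FM-derived RNA mass to
conditioned-media RNA mass for fraction f (a `CorrectionParams` input;
defaults in the generator: MV 0.02, EXO 0.05, RNP 0.15). Species absent
from the blank pass through unchanged; the floor at zero keeps abundances
physical. The exact functional form of the published correction is not
reproduced here; the subtraction form above is adopted as the simplest
rule consistent with describing the blank as a per-fraction background,
and it is exactly inverted by the generator's carry-over bookkeeping.
Whether to correct in fmol/ug or per-ml mass space is equivalent up to
the definition of `m_f`; the parameters are taken as measured inputs.

Enrichment between compartments is the pseudo-counted ratio
(ex + c) / (cell + c), with c defaulting to half the smallest nonzero
fmol across the compared tables so that species absent from one side get
finite, bounded ratios.

## Composition profiles

Class composition is the percentage of **annotated non-rRNA** reads per
unit: rRNA, spike-in and unannotated reads are excluded from the
denominator, because rRNA carry-over and unassigned reads differ wildly
between compartments and would otherwise dominate the comparison. Small
and long libraries are never pooled (different molecule populations and
spike designs). Transcript-length profiles take the top-N species by
fmol (default N = 500) with lexicographic id tie-break, and fractions are
compared to cells by a two-sided Mann-Whitney test (exact null for
n <= 50 per side, tie-corrected normal approximation otherwise).

## Inequality statistics

For a vector of abundances sorted in descending order, let F(k/N) be the
cumulative share of the top k species, linearly interpolated between
knots with F(0) = 0 (the complement of the Lorenz curve). The **evenness
factor** is 100 p* where p* solves F(p) = 1 - p; g(p) = F(p) - (1 - p)
rises strictly from -1 to +1, so the root exists and is unique. Because
F is piecewise linear, the bracketing segment is found from the sign of g
at the knots and the root is solved in closed form — deterministic and
exact to machine precision (uniform input satisfies F(p) = p and returns
exactly 50; extreme dominance approaches 0). The **Gini coefficient**
uses the sorted-rank formula G = 2 sum_i i x_(i) / (n sum x) - (n+1)/n,
which equals the pairwise mean absolute difference definition to 1e-12
(verified against a double-loop oracle in the tests). Both are
scale-invariant and respond monotonically to Pigou-Dalton transfers. The
top-share count reports the smallest k whose cumulative share reaches q
(default q = 0.8).

## Cross-culture heterogeneity

Within one RNA class and fraction, each species' reads are divided by the
culture's class total; the heterogeneity statistic is the sum of squared
deviations of these shares from their cross-culture mean ("chi^2" by
convention, though no division by expected values is performed — the
statistic is a plain SSE, which is what the name refers to throughout).
The species universe is the union over cultures, absences counting as
zero shares, so presence/absence differences are penalized. Cultures with
zero class reads are excluded with a warning; at least two must remain.
Extracellular-over-cellular fold changes beyond two-fold either way are
labeled increased/decreased. Top-k overlap (default k = 100) reports
pairwise and all-way intersections of the per-culture top-k species sets.

## Fragment analysis

Following the operational definition that a transcript quantified in the
small (15-65 nt insert) library is circulating as a fragment, the
fragment:full-length ratio of a species is the pseudo-counted ratio of
its small-library to long-library fmol. The 5' processing-site caller
smooths per-base coverage with a centered moving mean (window 3 nt),
scans the relative decrease (s_i - s_{i+1}) / s_i between adjacent
positions, and calls the position of the maximum decrease when it reaches
`min_drop` (default 0.5, conservative against the order-of-magnitude
drops typical of processed Y RNA and tRNA 5' fragments); ties resolve to
the 5'-most position. The fragment fraction is the share of raw depth at
or upstream of the called site. Centered smoothing displaces an ideal
step call by at most one position downstream, which is inside the +/-1 nt
tolerance used everywhere; with window 1 the ideal step is recovered
exactly. UTR/CDS enrichment takes per-culture log2 ratios (base
configurable) of extracellular over cellular alignment rates per region
and compares regions by unpaired two-sided Welch t-tests. Whether
alignment rates should be length-normalized is left to the caller: the
rates are consumed as given, computed against a shared read denominator
per unit.

## Stoichiometry

Per-EV arithmetic chains three exact conversions: mass per EV
(ag) = RNA yield (ng/ml) x 1e9 / particle concentration (per ml); the
non-rRNA share of that mass (default `non_rrna_mass_fraction` 0.1, an
input, since the mass split is measured, not derived); ribonucleotides
per EV = mass x N_A / M_nt with the mean single-stranded RNA residue
mass M_nt = 320.5 g/mol (configurable); and copies per
EV = fmol/ug x mass_ag x 6.022e-4. Copy levels are binned to the nearest
decade: b = round(-log10(copies)) meaning "one copy per ~10^b EVs", with
half-decade ties rounded toward the more abundant bin and anything above
one copy per EV reported as its own category. Class-level copies are the
sum over member species (additive by construction); the most abundant
member is reported alongside as a representative.

## Impactful-miRNA screen

For each miRNA, each extracellular fraction (donor cultures as
replicates) is compared with a recipient cell type (replicates):
log10 fold change of the means with the shared pseudo-count, and a
p-value from an unpaired two-sided Welch t-test on per-replicate
log10(fmol + c) values. Welch's unequal-variance form is the default
because extracellular and cellular dispersions differ systematically. A
fraction counts a "+" when the log10 fold change strictly exceeds 1.7
(10^1.7 ~ 50-fold) and p < 0.05; a miRNA is impactful with at least one
"+", and the cross-fraction tally (0-3) ranks the output. Raw p-values
are the default; per-fraction Benjamini-Hochberg adjustment is available
(`p_adjust="bh"`). The pseudo-count makes the knockout-recipient case
well-defined: a miRNA absent from the recipient is flagged whenever its
exRNA level exceeds c x 10^1.7. The fraction-vs-cell enrichment screen
pairs cultures, tests per-species mean log10 ratios against zero
(one-sample two-sided t), and calls enrichment when the mean is positive
at p < alpha; the sign restriction halves the nominal two-sided false
positive rate to about alpha/2.

## Synthetic-data generator

The generator emulates the study design — four donor cultures x four
fractions plus FM blanks, small and long libraries, spikes — with known
ground truth, so every stage is testable end to end without any download.

* **Abundances.** Per-species true cellular abundance is class median x
  log-normal(0, sigma), sigma = 1.5 (abundances span ~3 orders of
  magnitude, typical of a transcriptome). Class medians set the
  qualitative composition ranking; exact percentages are configuration,
  not constants.
* **Fraction effects.** Multiplicative class-by-fraction enrichments
  (defaults: miRNA 3x in exosomes, tRNA/Y-RNA fragments 3x in RNPs, mRNA
  2x in microvesicles, rRNA depleted extracellularly) reproduce the
  qualitative compartment signatures.
* **Dispersion.** Each (species, culture, fraction) gets one log-normal
  factor combining a culture-level dispersion (sigma 0.1 cellular, 0.5
  extracellular) with baseline species noise (sigma 0.35). The dispersion
  acts per species — a class-wide factor would cancel from within-class
  shares and could never raise the chi^2 heterogeneity — and the larger
  extracellular value makes extracellular fractions measurably more
  heterogeneous than cells, as the pipeline expects to detect. No
  dispersion estimates exist to calibrate against; the values are chosen
  once for testability and plausibility (35% replicate-level CV, ~50%
  culture-to-culture CV extracellularly).
* **Counts.** Observed reads per unit are one multinomial draw of the
  sequencing depth (default 2e5) over relative true abundances including
  the spikes — the simplest model consistent with count data and spike
  linearity. Spike normalization therefore recovers truth with relative
  error shrinking as depth^-1/2 (about 5% abundance-weighted at depth
  1e6).
* **Fresh media.** FM background species have fixed fmol levels and carry
  over into conditioned-media fractions as mass_ratio_f x fm_level,
  matching exactly what the blank correction subtracts;
  `plant_contaminant` adds a contaminant post hoc (levels add across
  plants) and re-draws counts from the updated truth.
* **Planted screen truth.** Impactful miRNAs are created at 10x the
  miRNA class median (the screen's genuine hits are abundant secreted
  species; a low-abundance plant would sit below the pseudo-count floor
  on the recipient side and cap the estimable fold change) with recipient
  level = base / fold. Recipient miRNomes otherwise perturb the cellular
  profile by a log-normal offset (sigma 0.5; 0 gives an exact null).
* **Coverage.** Synthetic profiles place `fragment_share` of the expected
  depth uniformly over positions 1..site and the rest downstream, with
  Poisson noise per base. Synthetic UTR/CDS rates start from (0.15,
  0.60, 0.25), bias the 3'UTR, renormalize, and add log-normal noise
  (sigma 0.1, the scale of a rate estimated from large read counts).

What the generator does **not** emulate: raw reads, alignment or
annotation error, ligation or GC bias, library-specific insert-size
effects, overdispersion beyond the log-normal x multinomial hierarchy,
and correlated species (no co-regulation). Passing tests therefore
demonstrate that the statistics recover the effects they define under
clean counting noise — not that real libraries are free of the biases the
wet-lab protocol addresses upstream.

## Problem sizes and determinism

Every stochastic step takes an explicit seed and is reproducible
bit-for-bit. Analyses in the test-suite and in `scripts/acceptance.py`
use problem sizes chosen per error budget: depth 1e6 for recovery-within-
5% checks; depth 4e6 with a ~12x carry-over for the media-correction
recovery (spike-scale noise multiplies the carry-over term, so the
post-correction error scales with carry/signal x depth^-1/2, giving
~6% sd against the 20% acceptance band); 200 replicate experiments at
depth 5e4 with a 60-miRNA panel for screen power and null calibration;
100 profiles at mean depth 100 for site recovery.

## Known limitations

* The blank-correction equation is an assumption (see above), exact only
  under the generator's own mass bookkeeping.
* `chi2` depends on the species-universe convention (union with zeros);
  restricting to shared species would give smaller values.
* The site caller reports a single dominant 5' site; multi-site profiles
  return only the steepest drop.
* Composition percentages are compositional data; no log-ratio transform
  is applied before comparing them.
* fmol/ug is semi-absolute: it is per microgram of total RNA, so changes
  in total RNA content between conditions rescale all species jointly.
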