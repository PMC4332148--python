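# Methods

This note documents the models and numerical choices behind
`proteoplex`: what the synthetic data emulates, how each statistic is
defined, which decisions were genuinely open, and what the validation
suite does and does not demonstrate.

## The generative model

The simulator (`proteoplex.simulate`) produces peptide-level
quantification tables from a fully specified ground truth, so every
downstream estimate can be checked against planted values.

**Complex composition.** Each cell line carries a total 20S amount and a
split of that pool over subtypes: sP20S (core + β1/β2/β5), iP20S
(core + β1i/β2i/β5i) and an intermediate form, modeled as the β1i/β5i
intermediate (core + β1i/β2/β5i). That choice of intermediate keeps β2i
exclusive to the iP20S, which is what makes β2i a clean immunoproteasome
proxy throughout. Regulators (19S, PA28αβ, PA28γ, PA200, PI31) bind each
subtype with an association propensity in [0, 1] — the expected bound
regulator per 20S particle. Intermediates default to the iP20S
propensity row, reflecting that intermediate subtypes associate with the
same regulators as the immunoproteasome. Default propensities (PA28αβ
0.9 iP / 0.05 sP; PI31 0.8 sP / 0.05 iP; PA200 0.7 sP / 0.05 iP; 19S
0.5/0.5; PA28γ 0.35/0.35) are calibration choices for recovery testing,
not measured biology.

**The purification.** An immunopurification captures `capture_yield`
(default 0.87) of the 20S pool with its bound regulators. Samples are
loaded at a nominal equal 20S amount; the immunoassay that sets the load
is imprecise, so every captured protein in a sample shares one loading
factor, drawn log-uniform with log-scale SD `loading_cv` (default 0.5).
This shared factor is deliberate and important: it is the variance
component that gives subunits of the same complex their high
cross-sample correlation, exactly as shared loading error does in real
purification series. It is bounded (log-uniform, not lognormal) because
raw-scale Pearson statistics are leverage-sensitive and real gross
mis-loads get caught and redone. Replicate biology enters as a
per-subtype lognormal factor with CV `biological_cv` (default 0.1).

**Peptide observation.** Each protein is observed through
`peptides_per_protein` (default 5) peptide ions whose
ionization-efficiency factors are drawn once (lognormal σ
`efficiency_sigma` = 0.45, roughly a 2× spread among a protein's top
peptides) and reused in every sample — the premise that makes TOP3 with
fixed reference peptides comparable across runs. Measurements get
multiplicative lognormal noise with CV `noise_cv` (default 0.2, using
σ = √ln(1+CV²) with the mean-one convention), dropout with probability
`missing_rate` (default 0.02 — reference peptides are a protein's most
intense, which rarely drop out), and a per-run drift factor (CV 0.2).
Eight isotopically labeled standard peptides are spiked at a constant
amount per run and perturbed only by the drift factor. Contaminant
proteins get per-sample abundances uncorrelated with everything, giving
the null background for specificity checks. S/N is reported as intensity
over a fixed noise floor.

**The cell-line panel.** Nine lines with inducible-20S shares
0.67, 0.65, 0.50 (hematopoietic: U937, KG1a, NB4) down to 0.025
(fibroblast), 2–3 replicates each, 24 purifications in total. The spread
of the inducible share — and its complement, the standard share — is the
biological signal the correlation analysis reads; the shares were chosen
once to span the range such cell panels actually cover.

**Gradient mode.** Complex species (26S, free 20S subtypes, a
PA28αβ-capped iP20S species, free 19S, a PA28γ-capped species) sediment
as Gaussians over 19 fraction indexes; a protein's noise-free profile is
the sum over species containing it. The planted PA28αβ–iP20S co-complex
carries most of the iP20S pool, so β2i's profile nearly coincides with
the PA28αβ reference while β1i/β5i are diluted by intermediate-containing
species — the configuration the screen is meant to detect. Contaminants
get broad (width 4–7 fractions) randomly centered profiles. Each
fraction of each replicate is an MS run with its own drift and spiked
standards.

**IFNγ time course.** Subtype amounts of a low-immuno HeLa-like base
(5% inducible) are scaled by a per-timepoint schedule (iP20S ×1/2/4/8,
sP20S ×1/0.85/0.7/0.5 at 0/24/48/72 h), three replicates per timepoint.
Starting from a low immuno baseline keeps the total 20S pool — the
ncP20S normalizer — approximately constant while the subtypes swing,
which is why the recovered normalized folds land near the planted 8×
and 0.5×.

All randomness flows from a single seed through a spawning seed
sequence, so outputs are bit-reproducible and stages can be re-run
independently.

## Quantification

Calibration rescales each run by the median, over its observed
standards, of (cross-sample mean of the standard ÷ its intensity in the
run). With the arithmetic-mean reference level, calibration fixes the
*relative* scale of runs: rescaling one run is absorbed up to a single
global constant (the reference level itself shifts), which is the
invariant the tests assert. A run without any observed standard is an
error, not a silent pass-through.

Reference peptides are the top three by summed calibrated intensity
across samples (missing = 0), ties broken lexicographically for
determinism. The PAI is the mean over the reference peptides *observed*
in a sample; averaging over observed peptides rather than imputing zeros
is the default because dropout at low intensity is stochastic, and the
zero-imputation variant is available (`missing_ref="zero"`) since the
correct convention is genuinely open.

## Gradient PCP

Profiles are per-protein PAIs over fractions, missing set to 0 (absence
of signal in a gradient is physics, not missing-at-random), divided by
the protein total. The reference profile is the member-median profile,
renormalized (median before renormalization — the alternative order
would be an equally defensible convention; this one is documented and
fixed). χ² uses the reference in the denominator and is therefore
asymmetric by design; fractions where the reference is zero are floored
at ε = 10⁻⁴ rather than dropped, because dropping would reward proteins
with mass where the reference has none. Replicate χ² values are combined
as the arithmetic mean and ranked ascending.

## AP-MS correlation and filtering

Correlations are Pearson on raw PAIs (no log), missing values
zero-filled in both vectors — with a fixed bait, non-detection reflects
low co-purification, and pairwise-complete deletion would bias r upward.
Records need n ≥ 3 samples; zero-variance vectors yield records flagged
undefined and excluded downstream rather than zero-filled. The
confidence filter interprets "r > 0.8" as signed Pearson r, so strong
anticorrelation does not pass. Within-complex R² summaries are reported
as mean ± SD across member pairs.

## Clustering

The UPGMA engine is written out so the merge order is fully specified:
equal-distance pairs resolve to the smallest node-index pair. Merge
heights equal the average pairwise dissimilarity between merged groups;
the suite verifies this against an exhaustive O(n⁴) oracle and against
scipy's `average` linkage. Supervised heat-map clustering uses Euclidean
distance on reference-R² row vectors with average linkage (no single
metric/linkage pair is canonical for such heat maps; both are
configurable), and
reference columns keep a fixed order. "Pearson (n)" PCA is
correlation-matrix PCA with population-variance standardization, the
convention that name carries in classical statistics suites; component
signs are fixed by making each component's largest-magnitude loading
positive. Pearson dissimilarity pairs with undefined r get the maximum
d = 2, with a report.

## Differential association

Ratios (regulator mean PAI ÷ ncP20S PAI) are computed per sample and
only then averaged, preserving replicate variability for the t-test.
The t-test is two-sided, two-sample, equal-variance ("Student"); Welch
is available via `equal_var=False`. No multiple-testing correction by
default, matching per-regulator significance reporting; a
Benjamini–Hochberg option exists and is off by default. The reference
condition is exactly 1 with p = 1 (a condition never differs from
itself).

## Validation studies and their scope

The recovery studies (`proteoplex.recovery`, exercised by the test suite
and `scripts/acceptance.py`) use 20 seeds per design and the default
study conditions above: 24 AP-MS samples for association recovery, two
19-fraction gradient replicates for the χ² screen, two pure-subtype
lines × 4 replicates with planted 4× (PA28αβ) and 8× (PI31) ratios for
the differential design, and 1000 two-condition null datasets for type-I
calibration of the t-test. These sizes keep the full suite under a few
minutes on one CPU while leaving the binomial success criteria
well-powered. Clustering recovery follows the same workflow a real
analysis would: proteins pass the confidence filter before being
clustered, and the
3-cluster cut is compared with the planted groups. Under the default
conditions both clustering routes recover the three planted groups in
roughly 97% of seeds; the residual failures are chance correlations at
n = 24 (occasionally one 19S subunit's noise realization tilts it toward
the standard-subtype pattern), which is the honest behaviour of the
method at this sample size, not a defect of the implementation.

## What passing tests do and do not show

The generator emulates the features the statistics actually consume:
shared per-run scale, fixed peptide efficiencies, multiplicative noise,
dropout, contaminant background, co-sedimentation geometry. It does not
emulate retention-time alignment errors, peptide misidentification,
protein-inference ambiguity, saturation or detector nonlinearity,
correlated contaminants (e.g. ribosomes co-purifying with everything),
or chromatographic peak-shape artifacts. Recovery on this synthetic data
therefore validates the statistical machinery — not the upstream
identification/quantification software, and not robustness to
systematically structured contamination. Real-data peculiarities the
pipeline inherits from its design choices (raw-scale Pearson's
sensitivity to high-leverage samples, the ncP20S normalizer's assumption
that total 20S is comparable across conditions) are discussed above
where each choice is made.

## Known limitations

* χ² values are not comparable across different ε choices when a
  reference has empty fractions; ε is configurable and recorded.
* The PIP filter's best-reference label uses argmax r over the three
  subtype references only, so a protein correlating mainly with, say,
  PA200 is labeled by its best 20S-subtype reference.
* UPGMA heights are guaranteed monotone only for well-behaved
  dissimilarities; violations would be reported, not silently fixed.
* The simulator's stoichiometry is 1 for every subunit within its
  complex; differential subunit stoichiometries (e.g. Rpn10 substoichiometry)
  are not modeled.
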