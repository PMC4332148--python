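# proteoplex

Quantitative analysis of proteasome complex heterogeneity from label-free
mass-spectrometry data, combining affinity-purification MS (AP-MS) and
protein correlation profiling (PCP).

## The problem

The 26S proteasome is not one machine but a family of them. A common 20S
core particle — eleven non-catalytic subunits (α1–α7, β3, β4, β6, β7,
collectively *ncP20S*) — is completed by either the standard catalytic
subunits β1/β2/β5 (*sP20S*) or the interferon-inducible β1i/β2i/β5i
(*iP20S*, the immunoproteasome), and capped by regulators (19S, PA28αβ,
PA28γ, PA200, PI31). Which regulator binds which 20S subtype is invisible
to ordinary interactomics, because a single purification mixes all
subtypes. `proteoplex` implements, end to end, the statistical workflow
that resolves this heterogeneity from peptide-level quantification
tables, together with a peptide-level synthetic-data generator so the
whole pipeline is testable without raw MS data.

## The methods at its core

* **TOP3 protein abundance index (PAI).** After per-run calibration on
  eight spiked isotopically labeled standard peptides, the PAI of protein
  *p* in sample *s* is the mean XIC area of its (at most) three reference
  peptides — the peptides with the highest summed intensity across all
  samples, fixed once per dataset.
* **χ² profile distance (PCP mode).** Across *F* gradient fractions,
  with sum-normalized profiles *x* (protein) and *p* (reference complex),
  χ²(x, p) = Σᵢ (xᵢ − pᵢ)² / pᵢ. Computed per biological replicate and
  averaged; a protein co-sedimenting with a complex scores near zero.
* **Cross-purification correlation (AP-MS mode).** Across a series of
  purifications from biologically diverse samples, subunits of one
  complex have proportional PAIs. Association is scored by the
  coefficient of determination R² between a protein's PAIs and a
  reference sub-complex abundance (median PAI of its detected members).
  A confidence filter keeps proteins with signed Pearson r > 0.8 against
  a 20S-subtype reference, ≥ 2 peptides, and median S/N > 10.
* **Clustering.** Supervised: hierarchical clustering of each protein's
  R² vector over the eight references (Euclidean, average linkage).
  Unsupervised: correlation-matrix ("Pearson (n)") PCA and UPGMA on the
  Pearson dissimilarity d = 1 − r of max-normalized PAIs.
* **Differential association.** A regulator's per-sample abundance (mean
  PAI of its proteins) is divided by the ncP20S abundance — a
  per-proteasome occupancy that cancels loading — and compared between
  conditions relative to a reference condition (set to 1) with a
  two-sided two-sample Student t-test.

## Worked example

Simulate the default AP-MS design — 9 human cell lines spanning 2–67%
inducible 20S content, 24 purifications in total — then quantify and
correlate:

```python
from proteoplex import GroundTruthModel, simulate_apms, quantify, default_catalog
from proteoplex.correlation import (
    build_reference_abundances, correlation_matrix, correlate, filter_pips,
)

model = GroundTruthModel(seed=1)
dataset = simulate_apms(model)
matrix, factors = quantify(dataset.peptide_table)
print(f"{len(matrix.proteins)} proteins x {len(matrix.samples)} purifications")

catalog, defs = default_catalog()
references, _ = build_reference_abundances(matrix, defs)
for a, b in [("iP20S", "PA28αβ"), ("sP20S", "PA28αβ"),
             ("sP20S", "PI31"), ("ncP20S", "19S")]:
    print(f"R2({a}, {b}) = {correlate(references.loc[a], references.loc[b]).r2:.2f}")

r2, r = correlation_matrix(matrix, references)
print(f"{len(filter_pips(matrix, r))} proteins pass the confidence filter")
```

prints

```
71 proteins x 24 purifications
R2(iP20S, PA28αβ) = 0.96
R2(sP20S, PA28αβ) = 0.03
R2(sP20S, PI31) = 0.94
R2(ncP20S, 19S) = 0.98
41 proteins pass the confidence filter
```

The planted structure is recovered: PA28αβ tracks the immunoproteasome
(R² = 0.96) and not the standard proteasome (R² = 0.03), PI31 tracks the
standard proteasome, and the 19S tracks total 20S. The same generator
drives the gradient screen (where β2i, the immuno-exclusive subunit,
shows the closest sedimentation profile to the PA28αβ reference) and the
two-cell-line differential design, where a planted 4× PA28αβ association
ratio is recovered as a relative normalized PAI of 3.88 (p = 1.4e-04 at
seed 1).

A command-line interface mirrors the library
(`proteoplex simulate|quantify|pcp|correlate|cluster|differential|run`);
`proteoplex run --mode apms --seed 1 --out run/` executes the whole
pipeline and writes a reproducibility manifest.

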