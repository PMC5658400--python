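# exrnatools

Quantitative analysis of extracellular RNA (exRNA) fractions for
cell-culture studies that separate conditioned media into microvesicles
(MV), exosomes (EXO) and non-vesicular ribonucleoprotein particles
(RNP), sequence them alongside the donor cells (CELL) as small- and
long-RNA libraries, and use fresh unconditioned media (FM) as a blank.
It is written for computational biologists who have annotated per-species
count tables in hand and want the downstream quantitative analysis to be
reproducible and testable.

The pipeline covers:

* **Spike-in semi-absolute quantification** — per-unit conversion of read
  counts to fmol per microgram of total RNA via the pooled-ratio spike
  estimator, `scale = Σ known_fmol / Σ spike reads`.
* **Fresh-media blank correction** — per-fraction mass-weighted
  subtraction `corrected = max(0, cm − m_f · fm)`, removing artifacts
  such as media-derived miRNAs that masquerade as exosomal cargo.
* **RNA-class composition** — percentages of annotated non-rRNA reads
  per culture x fraction x library, plus abundance-ranked
  transcript-length profiles.
* **Inequality statistics** — the evenness factor ε (the unique
  percentage such that ε% of species hold (100−ε)% of the abundance,
  solved on the interpolated top-share curve; 50 = perfectly even), the
  Gini coefficient G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), and top-share counts.
* **Cross-culture heterogeneity** — a sum-of-squared-errors statistic
  (χ²) on within-class abundance shares across cultures, fold changes vs
  the cellular fraction, and top-k species overlap.
* **Fragment analysis** — fragment:full-length ratios from paired
  small/long-library abundances, 5′ processing-site calling from
  per-base coverage, and UTR/CDS alignment-rate enrichment.
* **Copies-per-EV stoichiometry** — from bulk RNA yield and particle
  concentration to attograms, ribonucleotides and copies per vesicle,
  binned by nearest decade ("one copy per ~10^b EVs").
* **Impactful-miRNA screen** — volcano comparison of exRNA fractions
  against recipient-cell miRNomes (log₁₀ fold change > 1.7 ≈ 50-fold and
  Welch t-test p < 0.05), tallied across fractions.
* **Synthetic experiments** — a generator with known ground truth
  (log-normal abundances, class-specific fraction enrichments,
  multinomial counts over spiked relative abundances, FM carry-over,
  planted contaminants, planted impactful miRNAs, coverage profiles), so
  every stage is tested end to end with no external data.

## Worked example

```python
import numpy as np
from exrnatools import (
    EvPhysical, Fraction, Library, RnaClass, SimConfig,
    evenness_factor, generate_experiment, gini, n_top_for_share,
    quantify_dataset, stoichiometry_table,
)

config = SimConfig(seed=1)
dataset = generate_experiment(config)
quantified, fits = quantify_dataset(dataset.tables, config.spike_design)

unit = quantified.subset("GSC1", Fraction.EXO, Library.SMALL)
print(f"spike scale: {fits[('GSC1', 'EXO', 'SMALL')].scale:.4g} fmol/read")

mirna = unit.subset(rna_class=RnaClass.MIRNA).fmol_series().to_numpy()
print(f"evenness factor: {evenness_factor(mirna):.1f}   Gini: {gini(mirna):.3f}")
print(f"species covering 80% of the miRNome: {n_top_for_share(mirna, 0.8)}")

stoich = stoichiometry_table(unit, EvPhysical(8.9, 2e9, 0.1))
print(f"RNA per EV: {stoich.mass_per_ev_ag:.2f} ag ({stoich.nt_per_ev:.0f} non-rRNA nt)")
```

prints

```
spike scale: 0.01818 fmol/read
evenness factor: 22.7   Gini: 0.717
species covering 80% of the miRNome: 31
RNA per EV: 4.45 ag (836 non-rRNA nt)
```

Reading: the exosomal miRNome of this synthetic culture is strongly
unequal — 31 of 120 miRNA species carry 80% of the miRNA mass, the
evenness factor is 22.7 (50 would be perfectly even) and the Gini
coefficient 0.72. An EV preparation yielding 8.9 ng RNA per ml at 2×10⁹
particles per ml averages 4.45 ag of RNA per vesicle; with a tenth of
that mass being non-rRNA, each vesicle carries about 836 ribonucleotides
of informative sequence — i.e. most individual species are present at
well under one copy per EV.

A `click` CLI mirrors the library (`exrnatools simulate | validate |
quantify | compose | diversity | fragments | stoich | impact`); each
subcommand logs its parameters and the package version to a `run.log`
next to its output. See `docs/methods.md` for the models, parameter
defaults and numerical conventions.

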