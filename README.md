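# metaherit

Partitioning the heritability of blood metabolites in twin-family cohorts,
using published metabolite-SNP associations.

Roughly half of the variation in circulating metabolite levels is
heritable, but *which* genetic variation drives it differs by metabolite
class. A decade of metabolomics GWAS has produced large catalogs of
metabolite-associated SNPs; given genotyped twin-family data, those
catalogs can be turned into variance components that say how much of a
metabolite's heritability is already captured by known loci of its own
chemical super class, by loci of other classes, by the remaining
genome-wide SNPs, and by pedigree-associated variation that SNP arrays do
not tag. `metaherit` implements that analysis end to end for researchers
in genetic epidemiology and metabolomics: catalog curation, LD clumping,
GRM construction, multi-component GREML, and class-level meta-regression
— plus a synthetic twin-family cohort generator so every stage is
testable against known truth.

## The model

Per metabolite, a linear mixed model with four genetic relationship
matrices (GRMs) is fitted by unconstrained AI-REML:

    y = Xb + g1 + g2 + g3 + g4 + e
    V = V(G1)·A1 + V(G2)·A2 + V(G3)·A3 + V(G4)·A4 + V(e)·I

* **A1** — LD-weighted GRM from genome-wide SNPs with all metabolite loci
  and 50 kb flanks removed → `h2_g = V(G1)/Vp`
* **A2** — genome-wide GRM with genome sharing below 0.05 set to zero
  (close relatives only) → `h2_ped = V(G2)/Vp`
* **A3** — GRM of clumped lead loci for the metabolite's super class
  → `h2_class_hits = V(G3)/Vp`
* **A4** — GRM of the remaining (not-class) metabolite lead loci
  → `h2_notclass_hits = V(G4)/Vp`

with `Vp` the sum of all five components and the composites

    h2_metabolite_hits = h2_class_hits + h2_notclass_hits
    h2_snp   = h2_g + h2_metabolite_hits
    h2_total = h2_snp + h2_ped

Components are *not* constrained to be positive (negative estimates are
legal output); when the assembled V is not positive definite, eigenvalue
bending is applied before inversion. Standard errors of the composite
ratios come from Monte-Carlo resampling of the variance components from
the inverse average-information matrix; reduced models with the class
and/or not-class components dropped give likelihood-ratio tests.
Differences in heritability among metabolite classes are tested by
mixed-effect meta-regression with a sample-overlap/correlation dependence
matrix as random-effect structure and cluster-robust (CR2) inference.

## Worked example

`examples/03_partition_heritability.py` simulates a ~620-individual
twin-family cohort (MZ-twin, sibling and singleton families, 2000 block-LD
SNPs) with true fractions (h2_g, h2_ped, h2_class, h2_notclass) =
(0.30, 0.15, 0.06, 0.02), rebuilds the locus sets by clumping the emitted
association catalog, constructs the four GRMs, and fits the model:

```
converged: True after 10 iterations (bending applied: False)

composite heritabilities (truth in parentheses):
  h2_g                 +0.365 +/- 0.096  (0.3)
  h2_ped               +0.146 +/- 0.101  (0.15)
  h2_class_hits        +0.022 +/- 0.018  (0.06)
  h2_notclass_hits     +0.005 +/- 0.011  (0.02)
  h2_metabolite_hits   +0.027 +/- 0.021  (0.08)
  h2_snp               +0.392 +/- 0.097  (0.38)
  h2_total             +0.538 +/- 0.057  (0.53)
```

Each line is a variance fraction with its Monte-Carlo standard error:
this replicate attributes 53.8% of the metabolite's variance to genetic
sources, of which 2.7 points come from already-published metabolite loci.
The other scripts in `examples/` walk through cohort simulation, catalog
curation and clumping, panel preprocessing, meta-regression, and the
orchestrated pipeline (`metaherit run` on the command line).

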