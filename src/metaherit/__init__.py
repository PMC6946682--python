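"""metaherit: partitioning metabolite heritability in twin-family cohorts.

The package estimates, per metabolite, how much phenotypic variance is
attributable to four additive genetic sources fitted jointly by REML:

* ``V(G1)`` — genome-wide SNPs outside known metabolite loci (``h2_g``),
* ``V(G2)`` — pedigree-associated variance via a relatedness-thresholded
  GRM (``h2_ped``),
* ``V(G3)`` — loci previously associated with metabolites of the target
  super class (``h2_class_hits``),
* ``V(G4)`` — metabolite loci of other super classes (``h2_notclass_hits``),

plus composites ``h2_metabolite_hits = h2_class_hits + h2_notclass_hits``,
``h2_snp = h2_g + h2_metabolite_hits`` and ``h2_total = h2_snp + h2_ped``.
Upstream it curates published metabolite-SNP association catalogs, clumps
them into LD-independent loci, and builds LD-weighted genetic relationship
matrices; downstream it tests moderation of heritability by metabolite
class with dependence-aware mixed-effect meta-regression.

A synthetic twin-family cohort generator (``metaherit.simulate``) provides
data with the statistical structure the analysis assumes, so the whole
pipeline is testable without restricted cohort data.
"""

from metaherit.simulate import (
    FAMILY_TEMPLATES,
    GenotypeMatrix,
    MetabolitePanel,
    TrueArchitecture,
    emit_catalog,
    random_architecture,
    simulate_genotypes,
    simulate_metabolites,
    simulate_pedigree,
)
from metaherit.catalog import (
    ClassificationSummary,
    filter_snps,
    flag_hydrophobicity,
    hwe_test,
    load_catalog,
    summarize_catalog,
)
from metaherit.clumping import LocusSet, build_class_locus_sets, clump, ld_r2
from metaherit.grm import (
    GRM,
    build_grm,
    compute_ld_weights,
    exclude_regions,
    read_grm,
    threshold_grm,
    write_grm,
)
from metaherit.preprocess import (
    QCReport,
    impute_below_lod,
    impute_chained,
    mask_outliers,
    qc_filter,
    transform,
)
from metaherit.reml import (
    HeritabilityEstimate,
    LRTResult,
    VarianceModelFit,
    composite_heritabilities,
    fit_reml,
    lrt_reduced,
    mc_standard_errors,
    reml_loglik,
)
from metaherit.metareg import (
    MetaRegressionResult,
    build_dependence_matrix,
    fdr_adjust,
    fit_meta,
    robust_moderator_test,
)
from metaherit.pipeline import PipelineConfig, compare_covariate_models, run_pipeline

__version__ = "0.1.0"

__all__ = [
    "FAMILY_TEMPLATES",
    "GenotypeMatrix",
    "MetabolitePanel",
    "TrueArchitecture",
    "emit_catalog",
    "random_architecture",
    "simulate_genotypes",
    "simulate_metabolites",
    "simulate_pedigree",
    "ClassificationSummary",
    "filter_snps",
    "flag_hydrophobicity",
    "hwe_test",
    "load_catalog",
    "summarize_catalog",
    "LocusSet",
    "build_class_locus_sets",
    "clump",
    "ld_r2",
    "GRM",
    "build_grm",
    "compute_ld_weights",
    "exclude_regions",
    "read_grm",
    "threshold_grm",
    "write_grm",
    "QCReport",
    "impute_below_lod",
    "impute_chained",
    "mask_outliers",
    "qc_filter",
    "transform",
    "HeritabilityEstimate",
    "LRTResult",
    "VarianceModelFit",
    "composite_heritabilities",
    "fit_reml",
    "lrt_reduced",
    "mc_standard_errors",
    "reml_loglik",
    "MetaRegressionResult",
    "build_dependence_matrix",
    "fdr_adjust",
    "fit_meta",
    "robust_moderator_test",
    "PipelineConfig",
    "compare_covariate_models",
    "run_pipeline",
]
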