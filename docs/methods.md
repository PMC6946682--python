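# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `metaherit`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The four-component variance model

For a metabolite `y` measured on `n` related individuals with covariates
`X`, the marginal covariance is modelled as

    V = V(G1) A1 + V(G2) A2 + V(G3) A3 + V(G4) A4 + V(e) I.

The four relationship matrices separate four additive genetic sources:

| matrix | SNP set | role |
|---|---|---|
| A1 | genome-wide SNPs minus all metabolite loci, proxies and ±50 kb flanks | residual polygenic variance, `h2_g` |
| A2 | all genome-wide SNPs, off-diagonal sharing < 0.05 zeroed | pedigree-associated variance, `h2_ped` |
| A3 | clumped lead loci of the metabolite's super class | `h2_class_hits` |
| A4 | clumped lead loci of all other super classes | `h2_notclass_hits` |

The thresholding of A2 makes it (nearly) block diagonal by family, so
`V(G2)` is identified by the excess resemblance of close relatives over
what genome-wide allele sharing (A1) explains, while `V(G1)` is identified
by the GRM variation among nominally unrelated pairs. `h2_ped` absorbs any
source of excess familial resemblance that array SNPs do not tag — rare
and untyped variants, but also shared environment, dominance and
epistasis; `h2_total` can therefore be biased upward in cohorts of close
relatives, which is a property of the design, not of the estimator.

All GRMs use allele-frequency-standardized genotypes,

    A_ik = sum_j w_j (x_ij - 2p_j)(x_kj - 2p_j) / (2 p_j (1-p_j)) / sum_j w_j,

with frequencies estimated from the full sample (a founders-only option
exists). The per-SNP weights are the inverse of the local LD tally,
`w_j = 1 / sum_{k in ±100 kb} r^2_jk` (the sum includes `k = j`), which
halves the contribution of perfectly duplicated SNPs and down-weights
regions of redundant LD. This is a deliberately simple local-LD
correction with the same intent as iterative LD-adjustment solvers used
in the GREML literature; it is exercised by property tests (duplicated
SNPs get weight 1/2; isolated SNPs weight 1; agreement with a brute-force
pairwise-r² oracle), not by value comparisons against any external tool.
Thresholding of A2 is applied after LD weighting by default; the order is
a config switch because either convention is defensible.

## AI-REML

`fit_reml` maximizes the restricted likelihood with one
expectation-maximization warm-start iteration followed by
average-information updates, with step halving whenever a proposed step
would lower the likelihood (falling back to an EM step when halving
fails). Components are unconstrained; when the assembled V is not
positive definite, eigenvalues below 1e-8 of the largest are raised to
that floor ("bending") before inversion, and the fit records that this
happened. Convergence requires |Δ log L| < 1e-8 or relative parameter
change < 1e-8 within 100 iterations; starting values split the OLS
residual variance equally across components. The parameter covariance is
the inverse of the final average-information matrix.

Correctness anchors (run in `tests/test_acceptance.py`):

* estimates and log-likelihood agree with derivative-free Nelder-Mead
  maximization of the same restricted likelihood (1e-3 / 1e-4) on small
  two-component instances;
* on a balanced MZ-pair design with the expected relationship matrix the
  REML heritability equals the intraclass-correlation ANOVA estimator
  `(MSB − MSW)/(MSB + MSW)` to 1e-6;
* the likelihood surface is locally maximal at the fit under random
  perturbation, and the fit is invariant to reparameterization
  (duplicated GRMs with split variances) and equivariant under phenotype
  scaling.

## Composite heritabilities and their uncertainty

Ratios are formed from the variance components with `Vp` equal to the sum
of all five. Standard errors come from Monte-Carlo resampling: 10,000
draws from a multivariate normal centered at the estimates with the
inverse-AI covariance, recomputing every ratio (and `Vp`) per draw, and
taking standard deviations across draws. The default resamples
(V(G1), V(G3), V(G4)) jointly with V(G2) and V(e) held at their
estimates — the convention of the analysis this package operationalizes —
which means the default `h2_ped` standard error reflects only Vp
variation and understates that component's sampling variability;
`components="all"` resamples the full 5×5 covariance and is used wherever
honest uncertainty for `h2_ped` matters. Draws with |Vp| below 1e-12 of
the estimate are rejected and logged. On well-conditioned fits the MC
standard errors agree with the first-order delta method within a few
percent (the acceptance threshold is 15%).

LRTs for dropping V(G3), V(G4) or both refit the reduced model and refer
`max(0, 2 Δ log L)` to a chi-square with df equal to the number of
dropped components. Because the components are unconstrained, the null
value lies in the interior of the parameter space, so the usual
boundary-mixture reference distribution does not apply.

## Catalog curation and clumping

Catalogs are tab-delimited with one row per published metabolite-SNP
association (genome-wide significant, p < 5e-8). The loader rejects and
logs malformed rows, flags ratios, reports raw and deduplicated row
counts separately (published catalogs have been observed to disagree with
their own summaries at the margin), and warns when one rsID carries
conflicting positions (a mixed-genome-build symptom; build liftover is
out of scope). SNP filters follow a literal reading of the conventions
they mirror: MAF > 0.01 and imputation R² > 0.70 strict, HWE exclusion
strict at p < 1e-4. The HWE test is the exact conditional test (sum of
probabilities of heterozygote counts no more probable than observed,
given allele counts), which matches the chi-square approximation within
10% once expected counts reach 50 and returns 1 for monomorphic markers.
Hydrophobicity is labelled by comparing the octanol-water partition
measure against a configurable 1-octanol reference, strict on the
hydrophobic side, "unknown" for missing values.

Clumping is greedy: the smallest-p unassigned SNP becomes a lead; ties
break on (chromosome, bp, snp_id) for determinism; unassigned SNPs within
±500 kb on the same chromosome with dosage r² ≥ 0.10 become its proxies.
A SNP associated with several metabolites enters once with its minimum p.
LD is computed on an unrelated subset (one individual per family, capped
at 2500). Constant-dosage SNPs get r² = 0 with a warning so that
monomorphic-in-subset SNPs cannot become proxies. The class-specific list
is clumped first; its leads and proxies are removed from the pooled list
before the not-class clump. Output equals an independent brute-force
greedy implementation exactly on 100 random 200-SNP instances.

## Metabolite preprocessing

Fixed order, logged by the pipeline: QC filter → outlier masking →
below-LOD imputation → chained imputation → transform. Metabolites are
dropped when the mean per-batch coefficient of variation exceeds 25% or
the missing rate exceeds 5% (both strict). Entries censored below the
detection limit are treated as measurements, not missing data, for the
missing-rate bound, since they are recoverable by imputation with half
the detection limit (or half the minimum observed level when the limit is
unknown). Outliers beyond 5 SD of the mean are masked in a single pass;
whether masking precedes LOD imputation is not dictated by the
conventions this mirrors, so the order above is a documented choice.
Remaining missing values are filled by chained equations with
deterministic regression-mean draws (each incomplete metabolite regressed
on all others plus covariates, iterated to a 1e-4 sup-norm tolerance);
posterior-noise draws are deliberately not the default because
downstream REML testing needs reproducible completions. The normalizing
transform is inverse-normal with Blom offsets, Φ⁻¹((rank − 3/8)/(n + ¼)),
average ranks for ties (NMR-style platforms), or the natural logarithm
(MS-style platforms); the Blom variant is the common default in GWAS
phenotype preparation and is configurable.

## Meta-regression across metabolite classes

Per-metabolite heritability estimates `b_i` with known standard errors
are modelled as `b = Xβ + u + ε`, `cov(u) = τ² R`, `var(ε_i) = se_i²`,
where R is the dependence matrix — sample size on the diagonal,
`N12/√(n1·n2)·r` off-diagonal (N12 the participant overlap, r the
Spearman correlation) — rescaled to unit diagonal so that τ² is
identifiable (a matrix with sample sizes on the diagonal is not itself a
correlation structure; the raw mode is retained for sensitivity
analysis). τ² is estimated by bounded scalar REML. Moderation is tested
with a cluster-robust Wald F on the class dummies, clustered by
metabolite. The default sandwich is the CR2 bias-reduced estimator under
the fitted marginal covariance as working model, with
approximate-Hotelling (Satterthwaite-type) denominator degrees of
freedom; with ~10 metabolites per class the conventional m−p degrees of
freedom over-reject (measured ≈0.12 at nominal 0.05 in the packaged null
simulation), while the CR2 default calibrates into the acceptance band
[0.03, 0.08]. The conventional estimator remains available as
`method="cr1"`. BH-FDR adjustment is applied per test family.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Pedigrees** — nuclear-family templates (MZ pair ± parents, sibling
  pair ± parents, singletons) mixed by proportions; counts allocated by
  largest remainder so cohort sizes follow template arithmetic exactly.
  The default mix (35% MZ-pair, 35% sibling-pair with parents, 30%
  singletons) gives a realistic blend of close relatives and unrelateds
  for separating `h2_g` from `h2_ped`; real cohort compositions are not
  reproduced, so the mix is configuration, not a fixed constant.
* **Genotypes** — founder haplotypes from a per-block latent AR(1)
  allele-coupling (ρ = 0.8, block size 20, MAF uniform on [0.05, 0.5],
  5 kb spacing), giving tunable local r² for clumping and weighting
  tests; offspring receive one parental haplotype per block (block-level
  recombination); MZ co-twins are copied. Sibling and parent-offspring
  GRM entries average 0.5 (±0.05 at 10,000 SNPs).
* **Metabolites** — sum of background-polygenic, class-locus,
  notclass-locus, pedigree and residual components plus optional fixed
  covariate effects. Effects are interpreted per standardized genotype
  and every component is rescaled in-sample so its realized variance
  equals its requested fraction exactly; causal class/notclass loci are
  placed mutually unlinked (≥600 kb apart, via stratified placement) and
  background causal SNPs avoid the locus flanks so the purged A1 still
  covers them. The pedigree component is drawn by default from the
  expected pedigree relationship matrix (MZ 1, first-degree 0.5), which
  is what the fitted thresholded GRM approximates; a shared-family-
  constant variant (`pedigree_model="shared_env"`) is provided because
  pedigree-associated variance in real data may be exactly that, but it
  is not the default since its covariance structure (equal for all
  within-family pairs) does not match the fitted A2 and would bias
  recovery checks. Detection-limit censoring flags the bottom
  `lod_quantile` of each metabolite; additional values go missing at
  random.

What passing tests show — and what they do not: the generator matches the
model family the estimator assumes (additive effects, in-sample scaled,
single shared factor at most), so parameter-recovery results demonstrate
the correctness of the estimation machinery, not robustness to the
model misspecifications of real data (non-additivity, platform batch
structure beyond a label, metabolite cross-correlation, ancestry
structure, genotyping error).

## Problem sizes and numerical choices

The acceptance checks run at deliberately chosen scales: parameter
recovery uses 20 replicates of ~1200 individuals × 4000 SNPs in the test
suite (10 replicates in `scripts/acceptance.py`), where the mean of each
composite lands within ±0.05 of truth; oracle equivalence uses n = 30;
GRM diagnostics use 500 individuals × 10,000 SNPs; meta-regression
calibration uses 500 null datasets of 60 metabolites in 6 classes. Those
sizes give stable Monte-Carlo behavior for every assertion while keeping
a full run in the minutes range on one CPU.

Degenerate inputs are contracts, not accidents: constant phenotypes,
rank-deficient covariates, all-monomorphic SNP subsets, overlaps
exceeding sample sizes, and out-of-range p-values all raise; monomorphic
SNPs inside a subset are skipped with a warning; non-convergent REML fits
are returned flagged rather than raised, and non-invertible
covariance matrices are counted separately by the pipeline manifest,
mirroring how such analyses report their failure categories.

## Known limitations

* The LD weighting is a local stand-in, not a reimplementation of any
  specific iterative LD-adjustment algorithm; absolute heritability
  estimates under strongly heterogeneous LD may differ from tools using
  other weighting schemes.
* `h2_ped` conflates non-SNP genetic variance with shared environment by
  construction; the generator's kinship-based pedigree component makes
  recovery well-defined but real cohorts offer no such guarantee.
* The meta-regression treats per-metabolite standard errors as known.
* Genotype imputation, phasing, build liftover and ancestry-outlier
  detection are out of scope; inputs are assumed clean, single-build and
  ancestry-homogeneous.
* X-chromosome models, MAF/LD-stratified GREML and Haseman-Elston
  regression are not implemented.
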