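"""Partition a metabolite's heritability with the four-GRM GREML model.

One full replicate: simulate a ~700-individual twin-family cohort with
true fractions (h2_g, h2_ped, h2_class, h2_notclass) = (0.30, 0.15, 0.06,
0.02), rebuild the locus sets by clumping the emitted catalog, construct
the four LD-weighted GRMs, and fit the unconstrained four-component model
with Monte-Carlo standard errors and LRTs against reduced models.
"""

from metaherit import lrt_reduced, mc_standard_errors
from metaherit.pipeline import recovery_replicate

h2, fit = recovery_replicate(seed=5, n_families=200, n_snps=2000)

print("variance components (negative values are legal — unconstrained fit):")
for name, est in zip(fit.component_names, fit.estimates):
    print(f"  {name:<6} {est:+.4f}")
print(f"converged: {fit.converged} after {fit.n_iter} iterations "
      f"(bending applied: {fit.bent})")

# components="all" propagates the uncertainty of every variance component;
# the default mode holds V(G2) and V(e) at their estimates when resampling
ses = mc_standard_errors(fit, n_draws=10_000, seed=2, components="all")
print("\ncomposite heritabilities (truth in parentheses):")
for key, truth in [
    ("h2_g", 0.30), ("h2_ped", 0.15), ("h2_class_hits", 0.06),
    ("h2_notclass_hits", 0.02), ("h2_metabolite_hits", 0.08),
    ("h2_snp", 0.38), ("h2_total", 0.53),
]:
    print(f"  {key:<20} {getattr(h2, key):+.3f} +/- {ses[key]:.3f}  ({truth})")
# locus components and h2_total recover well per replicate; the split
# between h2_g and h2_ped is weakly identified at this cohort size and
# tightens with more families (their errors are anti-correlated)
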