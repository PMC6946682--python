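import numpy as np
import pandas as pd
import pytest

from metaherit import (
    build_class_locus_sets,
    build_grm,
    compute_ld_weights,
    emit_catalog,
    exclude_regions,
    random_architecture,
    simulate_genotypes,
    simulate_metabolites,
    simulate_pedigree,
    threshold_grm,
)
from metaherit.clumping import unrelated_subset
from metaherit.simulate import GenotypeMatrix

MIX = {"mz_pair_parents": 0.35, "sib_pair_parents": 0.35, "singleton": 0.30}
TRUE_FRACTIONS = (0.30, 0.15, 0.06, 0.02, 0.47)


@pytest.fixture(scope="session")
def cohort():
    """A mid-sized twin-family cohort shared across tests (~620 individuals,
    2000 SNPs, one metabolite with the reference architecture)."""
    ped = simulate_pedigree(200, MIX, seed=11)
    geno = simulate_genotypes(ped, 2000, seed=12)
    arch = random_architecture(geno, TRUE_FRACTIONS, n_class=5, n_notclass=5, seed=13)
    panel = simulate_metabolites(geno, arch, ped, seed=14, keep_components=True)
    return {"ped": ped, "geno": geno, "arch": arch, "panel": panel}


@pytest.fixture(scope="session")
def four_grms(cohort):
    """The four relationship matrices built from the shared cohort via the
    catalog -> clump -> GRM path."""
    ped, geno, arch = cohort["ped"], cohort["geno"], cohort["arch"]
    w = compute_ld_weights(geno)
    cat = emit_catalog(arch, geno.snp_meta, seed=15)
    cs, ns = build_class_locus_sets(cat, "lipids", geno,
                                    ld_individuals=unrelated_subset(ped))
    keep = exclude_regions(geno.snp_meta, [cs, ns])
    idx = {s: j for j, s in enumerate(geno.snp_meta["snp_id"])}
    g1 = build_grm(geno, keep, w)
    g2 = threshold_grm(build_grm(geno, None, w), 0.05)
    g3 = build_grm(geno, np.array([idx[s] for s in cs.leads]), w)
    g4 = build_grm(geno, np.array([idx[s] for s in ns.leads]), w)
    return [g1, g2, g3, g4]


def toy_genotypes(dosages, bp=None, chrom=None) -> GenotypeMatrix:
    """Hand-built genotype panel for boundary tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{j + 1}" for j in range(m)],
            "chromosome": ["1"] * m if chrom is None else chrom,
            "bp": np.arange(1, m + 1) * 1000 if bp is None else bp,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    return GenotypeMatrix(dosages, meta, [f"i{i + 1}" for i in range(n)])
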