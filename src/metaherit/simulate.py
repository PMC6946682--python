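"""Synthetic twin-family cohort generator.

Generates family-structured genotypes with block LD, true four-component
variance architectures, and metabolite panels with covariate, batch,
detection-limit and missingness effects, so that the curation, clumping,
GRM and GREML modules can be tested against known truth.

The generator emulates the *structure* of a twin-family biobank cohort
(MZ twin pairs, sibling pairs, parents, singletons clustered in nuclear
families), not the composition of any particular cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

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
]

# Family templates: (offspring kind, number of offspring, parents genotyped).
# Offspring of "mz" kind are monozygotic co-twins (identical genomes).
FAMILY_TEMPLATES: dict[str, dict] = {
    "mz_pair_parents": {"offspring": "mz", "n_offspring": 2, "parents": True},
    "mz_pair": {"offspring": "mz", "n_offspring": 2, "parents": False},
    "sib_pair_parents": {"offspring": "sib", "n_offspring": 2, "parents": True},
    "sib_pair": {"offspring": "sib", "n_offspring": 2, "parents": False},
    "singleton": {"offspring": None, "n_offspring": 0, "parents": False},
}


def template_size(name: str) -> int:
    """Number of genotyped individuals contributed by one family of this template."""
    t = FAMILY_TEMPLATES[name]
    if t["offspring"] is None:
        return 1
    return t["n_offspring"] + (2 if t["parents"] else 0)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with SNP metadata.

    dosages: individuals x SNPs, integer counts in {0,1,2} of the effect
    allele; snp_meta columns: snp_id, chromosome, bp, effect_allele,
    other_allele; bp strictly increasing within chromosome.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list[str]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_meta)):
            raise ValueError("dosage shape does not match ids / snp_meta")
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0,1,2}")
        for _, grp in self.snp_meta.groupby("chromosome", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                raise ValueError("bp must be increasing within chromosome")


@dataclass
class TrueArchitecture:
    """True generative variance architecture of one simulated metabolite.

    The three SNP index sets are pairwise disjoint; var_fractions are
    (f_g, f_ped, f_class, f_notclass, f_e), nonnegative, summing to 1.
    ``pedigree_model`` selects how the pedigree-associated component is
    generated: "kinship" draws it from the expected pedigree relationship
    matrix (MZ 1, first-degree 0.5), "shared_env" uses one value per family.
    """

    class_loci: np.ndarray
    notclass_loci: np.ndarray
    background_snps: np.ndarray
    class_effects: np.ndarray
    notclass_effects: np.ndarray
    background_effects: np.ndarray
    var_fractions: tuple[float, float, float, float, float]
    pedigree_model: str = "kinship"

    def validate(self) -> None:
        sets = [set(self.class_loci), set(self.notclass_loci), set(self.background_snps)]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("class/notclass/background SNP sets must be disjoint")
        vf = np.asarray(self.var_fractions, dtype=float)
        if vf.shape != (5,):
            raise ValueError("var_fractions must have 5 entries")
        if (vf < 0).any():
            raise ValueError("var_fractions must be nonnegative")
        if abs(vf.sum() - 1.0) > 1e-12:
            raise ValueError("var_fractions must sum to 1")
        for loci, eff in [
            (self.class_loci, self.class_effects),
            (self.notclass_loci, self.notclass_effects),
            (self.background_snps, self.background_effects),
        ]:
            if len(loci) != len(eff):
                raise ValueError("effect vector length must match its SNP set")

    def to_json(self, path) -> None:
        obj = {
            "class_loci": np.asarray(self.class_loci).tolist(),
            "notclass_loci": np.asarray(self.notclass_loci).tolist(),
            "background_snps": np.asarray(self.background_snps).tolist(),
            "class_effects": np.asarray(self.class_effects).tolist(),
            "notclass_effects": np.asarray(self.notclass_effects).tolist(),
            "background_effects": np.asarray(self.background_effects).tolist(),
            "var_fractions": list(self.var_fractions),
            "pedigree_model": self.pedigree_model,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


@dataclass
class MetabolitePanel:
    """Metabolite levels for a cohort, with censoring and missingness masks.

    ``values`` is individuals x metabolites with NaN for unobserved entries
    (either below the detection limit or missing at random); ``below_lod``
    marks entries censored at the detection limit; ``lod`` holds the
    per-metabolite limit (NaN when unknown).
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series
    batch: pd.Series
    platform: pd.Series
    class_label: pd.Series
    components: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.below_lod.shape != self.values.shape:
            raise ValueError("below_lod mask shape mismatch")
        # censored entries must be unobserved
        if (self.below_lod.to_numpy() & self.values.notna().to_numpy()).any():
            raise ValueError("below-LOD entries must be missing in values")
        if (self.batch.astype(str) == "").any():
            raise ValueError("batch labels must be non-empty")


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(
    n_families: int,
    family_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort of nuclear families from the template mix.

    family_mix maps template names (see FAMILY_TEMPLATES) to proportions
    summing to 1. Counts per template are allocated deterministically by
    largest remainder, so the individual count follows from template
    arithmetic; the seed only shuffles family order.

    Returns a DataFrame with columns individual_id, family_id, father_id,
    mother_id, sex, role; parents precede offspring within a family. For
    templates without genotyped parents, father/mother ids refer to
    un-genotyped founders absent from the table.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if family_mix is None:
        family_mix = {"mz_pair_parents": 0.3, "sib_pair_parents": 0.3, "singleton": 0.4}
    unknown = set(family_mix) - set(FAMILY_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown family templates: {sorted(unknown)}")
    props = np.array([family_mix[k] for k in family_mix], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("family_mix proportions must sum to 1")

    # largest-remainder allocation of family counts
    names = list(family_mix)
    raw = props * n_families
    counts = np.floor(raw).astype(int)
    rem = n_families - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1

    templates = np.repeat(names, counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(templates)

    rows = []
    for i, tname in enumerate(templates):
        t = FAMILY_TEMPLATES[tname]
        fam = f"F{i + 1:05d}"
        father, mother = f"{fam}_P1", f"{fam}_P2"
        if t["offspring"] is None:
            rows.append((f"{fam}_I1", fam, None, None, int(rng.integers(1, 3)), "singleton"))
            continue
        if t["parents"]:
            rows.append((father, fam, None, None, 1, "parent"))
            rows.append((mother, fam, None, None, 2, "parent"))
        if t["offspring"] == "mz":
            sex = int(rng.integers(1, 3))  # MZ co-twins share sex
            rows.append((f"{fam}_T1", fam, father, mother, sex, "mz_twin_a"))
            rows.append((f"{fam}_T2", fam, father, mother, sex, "mz_twin_b"))
        else:
            for j in range(t["n_offspring"]):
                rows.append(
                    (f"{fam}_S{j + 1}", fam, father, mother, int(rng.integers(1, 3)), "sibling")
                )
    return pd.DataFrame(
        rows, columns=["individual_id", "family_id", "father_id", "mother_id", "sex", "role"]
    )


# ---------------------------------------------------------------------------
# genotypes


def _founder_haplotypes(n_hap, freqs, block_sizes, rho, rng):
    """Block-AR(1) latent-Gaussian haplotypes: within a block the latent
    variables follow corr(i,j) = rho^|i-j|; thresholding at the allele
    frequency quantile yields alleles with tunable local r^2."""
    haps = np.empty((n_hap, freqs.size), dtype=np.int8)
    start = 0
    for s in block_sizes:
        idx = np.arange(s)
        corr = rho ** np.abs(idx[:, None] - idx[None, :])
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_hap, s)) @ chol.T
        thresh = norm.ppf(freqs[start : start + s])
        haps[:, start : start + s] = (z < thresh).astype(np.int8)
        start += s
    return haps


def simulate_genotypes(
    ped: pd.DataFrame,
    n_snps: int,
    block_size: int = 20,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    rho: float = 0.8,
    spacing_bp: int = 5000,
    chromosome: str = "1",
) -> GenotypeMatrix:
    """Simulate block-LD genotypes for a simulated pedigree.

    Founder haplotypes are drawn from a per-block autoregressive
    allele-coupling model (latent AR(1) with parameter ``rho``); offspring
    receive one parental haplotype per block (Mendelian transmission with
    block-level recombination); MZ co-twins are genotype-identical.
    Deterministic for a fixed seed.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    flip = rng.random(n_snps) < 0.5  # effect allele is the major one half the time
    freqs = np.where(flip, 1.0 - maf, maf)

    n_blocks = int(np.ceil(n_snps / block_size))
    block_sizes = [min(block_size, n_snps - b * block_size) for b in range(n_blocks)]

    families = ped.groupby("family_id", sort=False)
    # two founder parents per family with offspring, one founder for singletons
    fam_info = []
    n_founder_hap = 0
    for fam_id, grp in families:
        offspring = grp[grp["father_id"].notna()]
        if len(offspring) == 0:
            fam_info.append((fam_id, grp, None, n_founder_hap))
            n_founder_hap += 2
        else:
            fam_info.append((fam_id, grp, offspring, n_founder_hap))
            n_founder_hap += 4

    haps = _founder_haplotypes(n_founder_hap, freqs, block_sizes, rho, rng)

    dosages = np.empty((len(ped), n_snps), dtype=np.int8)
    row_of = {iid: i for i, iid in enumerate(ped["individual_id"])}

    def transmit(h1, h2):
        # one parental haplotype per LD block
        pick = rng.integers(0, 2, size=n_blocks)
        out = np.empty(n_snps, dtype=np.int8)
        start = 0
        for b, s in enumerate(block_sizes):
            src = h1 if pick[b] == 0 else h2
            out[start : start + s] = src[start : start + s]
            start += s
        return out

    for fam_id, grp, offspring, h0 in fam_info:
        if offspring is None:
            iid = grp["individual_id"].iloc[0]
            dosages[row_of[iid]] = haps[h0] + haps[h0 + 1]
            continue
        father_h = (haps[h0], haps[h0 + 1])
        mother_h = (haps[h0 + 2], haps[h0 + 3])
        for _, prow in grp[grp["father_id"].isna()].iterrows():
            src = father_h if prow["sex"] == 1 else mother_h
            dosages[row_of[prow["individual_id"]]] = src[0] + src[1]
        roles = offspring["role"].tolist()
        if roles and roles[0].startswith("mz_twin"):
            g = transmit(*father_h) + transmit(*mother_h)
            for iid in offspring["individual_id"]:
                dosages[row_of[iid]] = g
        else:
            for iid in offspring["individual_id"]:
                dosages[row_of[iid]] = transmit(*father_h) + transmit(*mother_h)

    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(n_snps)],
            "chromosome": chromosome,
            "bp": np.arange(1, n_snps + 1) * spacing_bp,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    return GenotypeMatrix(dosages, snp_meta, list(ped["individual_id"]))


# ---------------------------------------------------------------------------
# architecture and metabolites


def random_architecture(
    geno: GenotypeMatrix,
    var_fractions: tuple[float, float, float, float, float],
    n_class: int = 5,
    n_notclass: int = 5,
    background_fraction: float = 0.5,
    min_separation_bp: int = 600_000,
    flank_bp: int = 50_000,
    seed: int = 0,
    pedigree_model: str = "kinship",
) -> TrueArchitecture:
    """Draw a true architecture on a genotype panel.

    Class and notclass causal loci are placed mutually unlinked (at least
    ``min_separation_bp`` apart); background causal SNPs are a random
    ``background_fraction`` of the SNPs further than ``flank_bp`` from any
    locus, so that a locus-purged genome-wide GRM still covers them.
    """
    rng = np.random.default_rng(seed)
    bp = geno.snp_meta["bp"].to_numpy()
    chrom = geno.snp_meta["chromosome"].to_numpy()

    # stratified placement: one locus per equal segment of the SNP order,
    # jittered within the band that still guarantees the separation
    n_loci = n_class + n_notclass
    seg = geno.n_snps / n_loci
    spacing = np.median(np.diff(bp)) if geno.n_snps > 1 else min_separation_bp
    band = (seg * spacing - min_separation_bp) / (2 * spacing)
    if band < 0:
        raise ValueError("panel too small to place mutually unlinked loci")
    centers = (np.arange(n_loci) + 0.5) * seg
    jitter = rng.uniform(-band, band, size=n_loci)
    chosen = np.clip(np.round(centers + jitter).astype(int), 0, geno.n_snps - 1)
    for a, b in zip(chosen[:-1], chosen[1:]):
        if chrom[a] == chrom[b] and abs(int(bp[b]) - int(bp[a])) < min_separation_bp:
            raise ValueError("panel too small to place mutually unlinked loci")
    which = rng.permutation(n_loci)
    class_loci = np.sort(chosen[which[:n_class]]).astype(int)
    notclass_loci = np.sort(chosen[which[n_class:]]).astype(int)

    loci = np.concatenate([class_loci, notclass_loci])
    near = np.zeros(geno.n_snps, dtype=bool)
    for j in loci:
        near |= (chrom == chrom[j]) & (np.abs(bp - bp[j]) <= flank_bp)
    eligible = np.flatnonzero(~near)
    n_bg = max(1, int(round(background_fraction * eligible.size)))
    background = np.sort(rng.choice(eligible, size=n_bg, replace=False))

    arch = TrueArchitecture(
        class_loci=class_loci,
        notclass_loci=notclass_loci,
        background_snps=background,
        class_effects=rng.standard_normal(n_class),
        notclass_effects=rng.standard_normal(n_notclass),
        background_effects=rng.standard_normal(n_bg),
        var_fractions=tuple(float(v) for v in var_fractions),
        pedigree_model=pedigree_model,
    )
    arch.validate()
    return arch


def _standardized_dosages(dosages: np.ndarray) -> np.ndarray:
    x = dosages.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def expected_relationship_matrix(ped: pd.DataFrame) -> np.ndarray:
    """Expected additive relationship matrix from pedigree roles.

    Block diagonal per family: MZ co-twins 1, sibling and parent-offspring
    pairs 0.5, founder parents unrelated, diagonal 1.
    """
    n = len(ped)
    K = np.eye(n)
    idx = {iid: i for i, iid in enumerate(ped["individual_id"])}
    for _, grp in ped.groupby("family_id", sort=False):
        members = grp.to_dict("records")
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ra, rb = members[a], members[b]
                i, j = idx[ra["individual_id"]], idx[rb["individual_id"]]
                roles = {ra["role"], rb["role"]}
                if roles == {"mz_twin_a", "mz_twin_b"}:
                    r = 1.0
                elif "parent" in roles and roles != {"parent"}:
                    r = 0.5  # parent-offspring
                elif "parent" not in roles:
                    r = 0.5  # siblings (incl. MZ twin vs sibling)
                else:
                    r = 0.0  # the two founder parents
                K[i, j] = K[j, i] = r
    return K


def _unit_variance(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate component with zero variance")
    return x / sd


def simulate_metabolites(
    geno: GenotypeMatrix,
    archs: TrueArchitecture | list[TrueArchitecture],
    ped: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    covar_effects: dict[str, float] | None = None,
    lod_quantile: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    location: float = 0.0,
    batch_labels: pd.Series | None = None,
    platform: str = "nmr",
    class_label: str = "lipids",
    keep_components: bool = False,
) -> MetabolitePanel:
    """Generate metabolite levels from four-component additive architectures.

    Each metabolite is the sum of a background polygenic component, a
    class-locus component, a notclass-locus component, a pedigree-associated
    component, optional fixed covariate effects, and residual noise. Every
    stochastic component is rescaled in-sample so its variance equals its
    requested fraction exactly (effects are interpreted per standardized
    genotype). Values below the ``lod_quantile`` of the marginal
    distribution are censored (flagged below-LOD and set missing); a
    further ``missing_rate`` fraction is set missing at random.
    ``location`` shifts all metabolites by a constant (assay levels are
    positive in practice; a shift leaves every variance component intact).
    """
    if isinstance(archs, TrueArchitecture):
        archs = [archs]
    for a in archs:
        a.validate()
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    Z = _standardized_dosages(geno.dosages)

    fam_codes, fam_uniques = pd.factorize(ped["family_id"])
    K = expected_relationship_matrix(ped)
    # per-family Cholesky factors for the kinship pedigree component
    chol_blocks = []
    for f in range(len(fam_uniques)):
        rows = np.flatnonzero(fam_codes == f)
        chol_blocks.append((rows, np.linalg.cholesky(K[np.ix_(rows, rows)] + 1e-10 * np.eye(rows.size))))

    values = np.empty((n, len(archs)))
    components: dict[str, pd.DataFrame] = {}
    met_ids = [f"met{k + 1:03d}" for k in range(len(archs))]

    for k, arch in enumerate(archs):
        f_g, f_ped, f_class, f_notclass, f_e = arch.var_fractions
        comp = {}
        for name, frac, loci, eff in [
            ("background", f_g, arch.background_snps, arch.background_effects),
            ("class", f_class, arch.class_loci, arch.class_effects),
            ("notclass", f_notclass, arch.notclass_loci, arch.notclass_effects),
        ]:
            if frac > 0 and len(loci) == 0:
                raise ValueError(f"{name} fraction > 0 but no {name} SNPs")
            g = Z[:, loci] @ eff if len(loci) else np.zeros(n)
            comp[name] = np.sqrt(frac) * _unit_variance(g) if frac > 0 else np.zeros(n)

        if f_ped > 0:
            if arch.pedigree_model == "shared_env":
                u = rng.standard_normal(len(fam_uniques))[fam_codes]
            else:
                u = np.empty(n)
                for rows, L in chol_blocks:
                    u[rows] = L @ rng.standard_normal(rows.size)
            comp["pedigree"] = np.sqrt(f_ped) * _unit_variance(u)
        else:
            comp["pedigree"] = np.zeros(n)

        comp["noise"] = np.sqrt(f_e) * _unit_variance(rng.standard_normal(n)) if f_e > 0 else np.zeros(n)

        y = location + sum(comp.values())
        if covars is not None and covar_effects:
            for col, beta in covar_effects.items():
                y = y + beta * covars[col].to_numpy(dtype=float)
        values[:, k] = y
        if keep_components:
            components[met_ids[k]] = pd.DataFrame(comp, index=geno.individual_ids)

    vdf = pd.DataFrame(values, index=geno.individual_ids, columns=met_ids)

    lod = pd.Series(np.nan, index=met_ids)
    below = pd.DataFrame(False, index=vdf.index, columns=met_ids)
    if lod_quantile > 0:
        for m in met_ids:
            thr = float(vdf[m].quantile(lod_quantile))
            mask = vdf[m] < thr
            below[m] = mask
            lod[m] = thr
            vdf.loc[mask, m] = np.nan
    if missing_rate > 0:
        miss = rng.random(vdf.shape) < missing_rate
        vdf = vdf.mask(miss)

    if batch_labels is None:
        batch_labels = pd.Series(
            np.where(np.arange(n) % 2 == 0, "b1", "b2"), index=vdf.index, name="batch"
        )
    panel = MetabolitePanel(
        values=vdf,
        below_lod=below,
        lod=lod,
        batch=batch_labels,
        platform=pd.Series(platform, index=met_ids),
        class_label=pd.Series(class_label, index=met_ids),
        components=components,
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# catalog emission


def emit_catalog(
    archs: TrueArchitecture | list[TrueArchitecture],
    snp_meta: pd.DataFrame,
    class_labels: dict[str, str] | None = None,
    metabolite_ids: list[str] | None = None,
    study_n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit a published-association-style catalog from true architectures.

    One record per causal class/notclass SNP per metabolite, with genome-wide
    significant p-values (log-uniform below 5e-8), enabling round-trip tests
    of curation and clumping against known truth. ``class_labels`` maps the
    keys "class" and "notclass" to super-class names.
    """
    if isinstance(archs, TrueArchitecture):
        archs = [archs]
    if class_labels is None:
        class_labels = {"class": "lipids", "notclass": "organic acids"}
    if metabolite_ids is None:
        metabolite_ids = [f"met{k + 1:03d}" for k in range(len(archs))]
    rng = np.random.default_rng(seed)
    rows = []
    for met, arch in zip(metabolite_ids, archs):
        for kind, loci in [("class", arch.class_loci), ("notclass", arch.notclass_loci)]:
            for j in loci:
                meta = snp_meta.iloc[int(j)]
                pval = 10 ** rng.uniform(-30, np.log10(5e-8))
                rows.append(
                    {
                        "metabolite_id": met if kind == "class" else f"{met}_{kind}",
                        "hmdb_id": None,
                        "super_class": class_labels[kind],
                        "class": None,
                        "subclass": None,
                        "is_ratio": 0,
                        "snp_id": meta["snp_id"],
                        "chromosome": meta["chromosome"],
                        "bp": int(meta["bp"]),
                        "effect_allele": meta["effect_allele"],
                        "pvalue": pval,
                        "study_n": study_n,
                        "logS": None,
                    }
                )
    columns = [
        "metabolite_id", "hmdb_id", "super_class", "class", "subclass", "is_ratio",
        "snp_id", "chromosome", "bp", "effect_allele", "pvalue", "study_n", "logS",
    ]
    return pd.DataFrame(rows, columns=columns)
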