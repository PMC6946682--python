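"""Curation of published metabolite-SNP association catalogs.

Loads tab-delimited catalogs of genome-wide significant metabolite-SNP and
metabolite-ratio-SNP associations, classifies metabolites into super
classes, counts unique metabolites/ratios/SNPs, and applies SNP-level
quality filters (minor allele frequency, imputation quality, Hardy-Weinberg
equilibrium).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationSummary",
    "compute_snp_stats",
    "filter_snps",
    "flag_hydrophobicity",
    "hwe_test",
    "load_catalog",
    "summarize_catalog",
]

REQUIRED_COLUMNS = ["metabolite_id", "snp_id", "chromosome", "bp", "pvalue"]
OPTIONAL_COLUMNS = [
    "hmdb_id", "super_class", "class", "subclass", "is_ratio",
    "effect_allele", "study_n", "logS",
]

#: Reference octanol-water partition measure of 1-octanol itself, on the
#: log10 water/octanol concentration-ratio scale (lower = more hydrophobic);
#: metabolites strictly below the reference are labelled hydrophobic. The
#: threshold is configurable since catalogs differ in the exact scale used.
OCTANOL_LOGS = -3.0


@dataclass
class ClassificationSummary:
    """Counts of unique metabolites/ratios/SNPs and per-super-class totals."""

    n_rows: int
    n_rows_dedup: int
    n_unique_metabolites_or_ratios: int
    n_unique_metabolites: int
    n_unique_ratios: int
    n_unique_snps: int
    n_classified: int
    per_super_class: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if sum(self.per_super_class.values()) != self.n_classified:
            raise ValueError("per-class counts must sum to classified total")


def load_catalog(path) -> pd.DataFrame:
    """Load a tab-delimited association catalog.

    Mandatory columns: metabolite_id, snp_id, chromosome, bp, pvalue.
    Rows with unparseable bp or pvalue, or pvalue outside (0, 1], are
    rejected and logged with their 1-based file line number. Ratios are
    flagged by the is_ratio column when present, else by a "/" in the
    metabolite id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, na_values=["NA", ""])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} is missing mandatory column(s): {missing}")

    df["_line"] = df.index + 2  # header is line 1
    bad = pd.Series(False, index=df.index)
    bp = pd.to_numeric(df["bp"], errors="coerce")
    pv = pd.to_numeric(df["pvalue"], errors="coerce")
    bad |= bp.isna() | (bp < 1)
    bad |= pv.isna() | (pv <= 0) | (pv > 1)
    bad |= df["metabolite_id"].isna() | df["snp_id"].isna()
    for line in df.loc[bad, "_line"]:
        logger.warning("catalog %s: rejected malformed row at line %d", path, line)
    df = df[~bad].copy()
    df["bp"] = bp[~bad].astype(int)
    df["pvalue"] = pv[~bad]

    if "is_ratio" in df.columns:
        df["is_ratio"] = df["is_ratio"].fillna(0).astype(int).astype(bool)
    else:
        df["is_ratio"] = df["metabolite_id"].str.contains("/", regex=False)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    # warn on duplicate rsIDs mapped to conflicting positions (mixed builds)
    pos = df.groupby("snp_id")[["chromosome", "bp"]].nunique()
    conflicted = pos[(pos["chromosome"] > 1) | (pos["bp"] > 1)].index
    for snp in conflicted:
        logger.warning("catalog %s: SNP %s has conflicting positions", path, snp)

    return df.drop(columns=["_line"]).reset_index(drop=True)


def summarize_catalog(records: pd.DataFrame) -> ClassificationSummary:
    """Count unique metabolites, ratios and SNPs, and unique metabolites per
    super class. Ratios and unclassified metabolites are excluded from the
    per-class counts. Raw and fully-deduplicated row counts are both
    reported, since published catalogs can contain duplicated rows."""
    n_rows = len(records)
    n_dedup = len(records.drop_duplicates(subset=["metabolite_id", "snp_id", "pvalue"]))
    is_ratio = records["is_ratio"].astype(bool)
    mets = records.loc[~is_ratio, "metabolite_id"]
    ratios = records.loc[is_ratio, "metabolite_id"]

    classified = records.loc[~is_ratio & records["super_class"].notna()]
    per_class = (
        classified.groupby("super_class")["metabolite_id"].nunique().sort_values(ascending=False)
    )
    summary = ClassificationSummary(
        n_rows=n_rows,
        n_rows_dedup=n_dedup,
        n_unique_metabolites_or_ratios=records["metabolite_id"].nunique(),
        n_unique_metabolites=mets.nunique(),
        n_unique_ratios=ratios.nunique(),
        n_unique_snps=records["snp_id"].nunique(),
        n_classified=int(per_class.sum()),
        per_super_class=per_class.to_dict(),
    )
    summary.validate()
    return summary


def flag_hydrophobicity(logS: float | None, threshold: float = OCTANOL_LOGS) -> str:
    """Label a metabolite hydrophobic or hydrophilic by its octanol-water
    partition measure. "More hydrophobic than 1-octanol" is read strictly:
    a value exactly at the reference is hydrophilic; a missing value yields
    "unknown"."""
    if logS is None or (isinstance(logS, float) and math.isnan(logS)):
        return "unknown"
    return "hydrophobic" if logS < threshold else "hydrophilic"


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg equilibrium test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed table. Monomorphic markers return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError("genotype counts must be nonnegative with positive total")
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # copies of allele a
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0

    rare = min(na, nb)
    # log P(n_het | allele counts) up to a common constant
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    logp = (
        hets * math.log(2)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - rare - hets) / 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def compute_snp_stats(geno) -> pd.DataFrame:
    """Per-SNP MAF, genotype counts and exact HWE p from a genotype panel.

    imputation_r2 is set to 1 for directly simulated genotypes; supply the
    column externally for imputed data.
    """
    d = geno.dosages
    n = d.shape[0]
    n2 = (d == 2).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n0 = n - n1 - n2
    freq = (2 * n2 + n1) / (2 * n)
    maf = np.minimum(freq, 1 - freq)
    hwe = [hwe_test((int(a), int(b), int(c))) for a, b, c in zip(n0, n1, n2)]
    return pd.DataFrame(
        {
            "snp_id": geno.snp_meta["snp_id"].to_numpy(),
            "maf": maf,
            "imputation_r2": 1.0,
            "hwe_p": hwe,
            "n_AA": n0,
            "n_Aa": n1,
            "n_aa": n2,
        }
    )


def filter_snps(
    records: pd.DataFrame,
    stats: pd.DataFrame,
    maf_min: float = 0.01,
    r2_min: float = 0.70,
    hwe_alpha: float = 1e-4,
) -> pd.DataFrame:
    """Apply the SNP quality filters to catalog records.

    Retains records whose SNP has maf > maf_min, imputation_r2 > r2_min
    (both strict) and HWE p >= hwe_alpha (exclusion strict "<"). Records
    whose SNP is absent from the stats table, or flagged multi-allelic
    (column ``is_multiallelic``), are dropped and logged.
    """
    st = stats.set_index("snp_id")
    present = records["snp_id"].isin(st.index)
    n_absent = int((~present).sum())
    if n_absent:
        logger.warning("filter_snps: %d records dropped (SNP not in stats)", n_absent)
    rec = records[present].copy()
    s = st.loc[rec["snp_id"]]
    keep = (
        (s["maf"].to_numpy() > maf_min)
        & (s["imputation_r2"].to_numpy() > r2_min)
        & (s["hwe_p"].to_numpy() >= hwe_alpha)
    )
    if "is_multiallelic" in st.columns:
        keep &= ~s["is_multiallelic"].fillna(False).to_numpy().astype(bool)
    return rec[keep].reset_index(drop=True)
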