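"""LD clumping of association lists into lead loci and proxies.

Greedy p-value-ordered clumping: the most significant unassigned SNP
becomes a lead; unassigned SNPs on the same chromosome within the radius
and with squared dosage correlation above the threshold become its
proxies. Class-specific and not-class locus sets are produced by clumping
the in-class associations first, removing their leads and proxies from the
pooled list, and clumping the remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metaherit.simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["LocusSet", "build_class_locus_sets", "clump", "ld_r2", "unrelated_subset"]


@dataclass
class LocusSet:
    """Clumped lead SNPs with their LD proxies for one locus list."""

    label: str
    leads: list[str]
    proxies: dict[str, list[str]] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def all_snps(self) -> set[str]:
        out = set(self.leads)
        for v in self.proxies.values():
            out |= set(v)
        return out

    def to_table(self) -> pd.DataFrame:
        rows = [{"lead": l, "proxy": None} for l in self.leads]
        for lead, prox in self.proxies.items():
            rows += [{"lead": lead, "proxy": p} for p in prox]
        return pd.DataFrame(rows, columns=["lead", "proxy"])


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    A constant vector has undefined correlation; by convention it yields
    r^2 = 0 with a warning, so monomorphic-in-subset SNPs cannot become
    proxies.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.size < 2:
        raise ValueError("dosage vectors must have equal length >= 2")
    s1, s2 = g1.std(), g2.std()
    if s1 == 0 or s2 == 0:
        logger.warning("ld_r2: constant dosage vector; returning 0")
        return 0.0
    r = float(np.corrcoef(g1, g2)[0, 1])
    return r * r


def unrelated_subset(ped: pd.DataFrame, max_n: int | None = 2500) -> list[str]:
    """One individual per family (first listed), capped at ``max_n``, as the
    reference panel for LD computation."""
    firsts = ped.groupby("family_id", sort=False)["individual_id"].first().tolist()
    return firsts[:max_n] if max_n else firsts


def _min_p_per_snp(assoc: pd.DataFrame) -> pd.DataFrame:
    """A SNP associated with several metabolites enters clumping once with
    its minimum p across metabolites; ties then break on (chromosome, bp)
    and snp_id for determinism."""
    per = assoc.groupby("snp_id", as_index=False).agg(
        pvalue=("pvalue", "min"),
        chromosome=("chromosome", "first"),
        bp=("bp", "first"),
    )
    return per.sort_values(
        ["pvalue", "chromosome", "bp", "snp_id"], kind="stable"
    ).reset_index(drop=True)


def clump(
    assoc: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_threshold: float = 0.10,
    radius_bp: int = 500_000,
    ld_individuals: list[str] | None = None,
    label: str = "loci",
) -> LocusSet:
    """Greedy LD clumping of an association list against a genotype panel.

    SNPs absent from the panel are dropped with a warning. LD is computed
    on ``ld_individuals`` (default: all individuals in the panel); a
    candidate within ``radius_bp`` of the lead on the same chromosome and
    with r^2 >= ``r2_threshold`` is absorbed as a proxy.
    """
    snp_index = {s: j for j, s in enumerate(geno.snp_meta["snp_id"])}
    per_snp = _min_p_per_snp(assoc)
    dropped = [s for s in per_snp["snp_id"] if s not in snp_index]
    if dropped:
        logger.warning("clump: %d SNP(s) absent from panel, dropped", len(dropped))
    per_snp = per_snp[per_snp["snp_id"].isin(snp_index)].reset_index(drop=True)

    if ld_individuals is not None:
        rows = [geno.individual_ids.index(i) for i in ld_individuals]
        dos = geno.dosages[rows]
    else:
        dos = geno.dosages

    cols = per_snp["snp_id"].map(snp_index).to_numpy()
    chrom = per_snp["chromosome"].astype(str).to_numpy()
    bp = per_snp["bp"].to_numpy(dtype=np.int64)

    unassigned = np.ones(len(per_snp), dtype=bool)
    leads: list[str] = []
    proxies: dict[str, list[str]] = {}
    for i in range(len(per_snp)):  # rows already in p-value / tie-break order
        if not unassigned[i]:
            continue
        unassigned[i] = False
        lead = per_snp.at[i, "snp_id"]
        leads.append(lead)
        cand = np.flatnonzero(
            unassigned & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= radius_bp)
        )
        if cand.size == 0:
            proxies[lead] = []
            continue
        g_lead = dos[:, cols[i]]
        prox = []
        for k in cand:
            if ld_r2(g_lead, dos[:, cols[k]]) >= r2_threshold:
                unassigned[k] = False
                prox.append(per_snp.at[int(k), "snp_id"])
        proxies[lead] = prox
    return LocusSet(
        label=label,
        leads=leads,
        proxies=proxies,
        dropped=dropped,
        params={"r2_threshold": r2_threshold, "radius_bp": radius_bp,
                "n_ld_individuals": dos.shape[0]},
    )


def build_class_locus_sets(
    records: pd.DataFrame,
    super_class: str,
    geno: GenotypeMatrix,
    r2_threshold: float = 0.10,
    radius_bp: int = 500_000,
    ld_individuals: list[str] | None = None,
) -> tuple[LocusSet, LocusSet]:
    """Clump the in-class association list, then clump the remaining
    associations after removing the class leads and proxies, yielding the
    class-specific and not-class locus sets."""
    in_class = records[records["super_class"] == super_class]
    if len(in_class) == 0:
        logger.warning("build_class_locus_sets: no records for %s", super_class)
        class_set = LocusSet(label=f"class-specific:{super_class}", leads=[])
    else:
        class_set = clump(
            in_class, geno, r2_threshold, radius_bp, ld_individuals,
            label=f"class-specific:{super_class}",
        )
    class_snps = class_set.all_snps
    rest = records[~records["snp_id"].isin(class_snps)]
    if len(rest) == 0:
        logger.warning("build_class_locus_sets: not-class list empty for %s", super_class)
        notclass_set = LocusSet(label=f"not-class:{super_class}", leads=[])
    else:
        notclass_set = clump(
            rest, geno, r2_threshold, radius_bp, ld_individuals,
            label=f"not-class:{super_class}",
        )
    return class_set, notclass_set


def write_locus_set(path_prefix: str, locus_set: LocusSet) -> None:
    """Serialize as tab-delimited lead/proxy table plus JSON params sidecar."""
    import json

    locus_set.to_table().to_csv(f"{path_prefix}.tsv", sep="\t", index=False, na_rep="NA")
    with open(f"{path_prefix}.params.json", "w") as fh:
        json.dump({"label": locus_set.label, "dropped": locus_set.dropped,
                   **locus_set.params}, fh, indent=1)
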