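"""Genotype and panel I/O.

PLINK .bed/.bim/.fam and plain-text VCF writing/reading for the simulated
cohorts, plus tab-delimited panel/covariate round-trips. The .bed codec
covers the SNP-major variant-by-variant 2-bit encoding (00 = two copies of
allele 1, 10 = heterozygous, 11 = zero copies, 01 = missing); dosages here
count allele 1 (the .bim A1 column).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metaherit.simulate import GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "write_vcf",
    "read_panel_tsv",
    "write_panel_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> allele-1 dosage (-1 = missing)
_CODE_TO_DOSE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(prefix: str, geno: GenotypeMatrix, ped: pd.DataFrame | None = None) -> None:
    """Write a genotype matrix as PLINK prefix.bed/.bim/.fam."""
    n, m = geno.dosages.shape
    nbytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((m, nbytes), dtype=np.uint8)
        for j in range(m):
            col = geno.dosages[:, j]
            codes = np.array([_DOSE_TO_CODE[int(d)] for d in col], dtype=np.uint8)
            for i, c in enumerate(codes):
                buf[j, i >> 2] |= c << ((i & 3) * 2)
        fh.write(buf.tobytes())

    bim = geno.snp_meta
    with open(f"{prefix}.bim", "w") as fh:
        for _, r in bim.iterrows():
            fh.write(
                f"{r['chromosome']}\t{r['snp_id']}\t0\t{r['bp']}\t"
                f"{r['effect_allele']}\t{r['other_allele']}\n"
            )

    with open(f"{prefix}.fam", "w") as fh:
        if ped is not None:
            idx = ped.set_index("individual_id")
            for iid in geno.individual_ids:
                r = idx.loc[iid]
                fid = r["family_id"]
                fa = r["father_id"] if pd.notna(r["father_id"]) else "0"
                mo = r["mother_id"] if pd.notna(r["mother_id"]) else "0"
                fh.write(f"{fid}\t{iid}\t{fa}\t{mo}\t{r['sex']}\t-9\n")
        else:
            for iid in geno.individual_ids:
                fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read PLINK prefix.bed/.bim/.fam into a GenotypeMatrix.

    Missing genotypes are not representable in the integer dosage matrix and
    raise a ValueError.
    """
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "bp", "effect_allele", "other_allele"],
        dtype={"chromosome": str},
    )
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    nbytes = (n + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
        raw = fh.read()
    expected = m * nbytes
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed truncated: expected {expected} data bytes, found {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=np.uint8).reshape(m, nbytes)
    # unpack 2-bit codes
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, nbytes * 4)[:, :n]
    dosages = _CODE_TO_DOSE[codes].T.copy()
    if (dosages < 0).any():
        raise ValueError("missing genotypes present; dosage matrix requires complete data")
    meta = bim[["snp_id", "chromosome", "bp", "effect_allele", "other_allele"]].copy()
    return GenotypeMatrix(dosages.astype(np.int8), meta, list(fam["individual_id"]))


def write_vcf(path: str, geno: GenotypeMatrix) -> None:
    """Write the genotype matrix as a minimal plain-text VCFv4.2.

    Dosages count the ALT allele, so REF is the other allele and the
    genotype field is 0/0, 0/1 or 1/1.
    """
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = geno.snp_meta["chromosome"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        for j, r in geno.snp_meta.iterrows():
            fields = [
                str(r["chromosome"]), str(r["bp"]), r["snp_id"],
                r["other_allele"], r["effect_allele"], ".", "PASS", ".", "GT",
            ]
            fields += [gt[int(d)] for d in geno.dosages[:, j]]
            fh.write("\t".join(fields) + "\n")


def write_panel_tsv(path: str, values: pd.DataFrame, index_label: str = "individual_id") -> None:
    values.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_panel_tsv(path: str, index_col: str = "individual_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])
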