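"""Construction of weighted genetic relationship matrices.

Builds the four relationship matrices of the variance-partitioning model:

* A1 — LD-weighted genome-wide GRM with metabolite loci and their flanking
  regions excluded (drives ``V(G1)``, the residual polygenic variance);
* A2 — genome-wide GRM with small off-diagonal genome-sharing set to zero,
  so only close relatives contribute (drives ``V(G2)``, the
  pedigree-associated variance);
* A3 / A4 — GRMs restricted to class-specific / not-class metabolite lead
  loci (drive ``V(G3)`` / ``V(G4)``).

Per-SNP weights are the inverse of the local LD tally (1 / sum of r^2 with
SNPs in a window, the sum including the SNP itself), down-weighting SNPs in
regions of redundant LD so that uneven and long-range LD does not
over-count genome sharing.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metaherit.clumping import LocusSet
from metaherit.simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GRM",
    "build_grm",
    "compute_ld_weights",
    "exclude_regions",
    "read_grm",
    "threshold_grm",
    "write_grm",
]


@dataclass
class GRM:
    """Symmetric relatedness matrix with provenance.

    ``n_snps`` is the number of SNPs behind every pair (complete-data
    construction, so a scalar); ``weights`` are the per-SNP nonnegative
    weights used in the weighted average of standardized genotype products.
    """

    matrix: np.ndarray
    ids: list[str]
    n_snps: int
    weights: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GRM shape does not match ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM entries must be finite")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ValueError("GRM must be symmetric to 1e-12")


def compute_ld_weights(geno: GenotypeMatrix, window_bp: int = 100_000) -> np.ndarray:
    """Inverse-local-LD SNP weights: w_j = 1 / sum_k r^2_jk over SNPs k on
    the same chromosome with |bp_k - bp_j| <= window_bp, the sum including
    k = j, so 0 < w_j <= 1. Two perfectly duplicated SNPs each receive
    weight 1/2, halving the double-counted signal."""
    bp = geno.snp_meta["bp"].to_numpy(dtype=np.int64)
    chrom = geno.snp_meta["chromosome"].astype(str).to_numpy()
    x = geno.dosages.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    n = x.shape[0]
    m = x.shape[1]
    weights = np.empty(m)
    for j in range(m):
        in_win = (chrom == chrom[j]) & (np.abs(bp - bp[j]) <= window_bp)
        nbrs = np.flatnonzero(in_win)
        r = x[:, nbrs].T @ x[:, j] / n
        weights[j] = 1.0 / max(np.sum(r * r), 1.0)  # self term is 1 unless monomorphic
    return weights


def build_grm(
    geno: GenotypeMatrix,
    snp_subset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    founders_only_freq: bool = False,
    founder_rows: np.ndarray | None = None,
    label: str = "grm",
) -> GRM:
    """Weighted allele-frequency-standardized GRM.

    A_ik = sum_j w_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j)) / sum_j w_j

    with allele frequencies p_j estimated from the sample (optionally from
    founder rows only). Monomorphic SNPs in the subset are skipped with a
    warning; an all-monomorphic subset is an error. ``weights`` is indexed
    over the full panel.
    """
    m_total = geno.n_snps
    subset = np.arange(m_total) if snp_subset is None else np.asarray(snp_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("SNP subset is empty")
    w_full = np.ones(m_total) if weights is None else np.asarray(weights, dtype=float)
    if (w_full < 0).any():
        raise ValueError("weights must be nonnegative")

    x = geno.dosages[:, subset].astype(float)
    freq_rows = x if not founders_only_freq else x[founder_rows]
    p = freq_rows.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono == subset.size:
        raise ValueError("all SNPs in subset are monomorphic")
    if n_mono:
        logger.warning("build_grm: skipping %d monomorphic SNP(s)", n_mono)
    x = x[:, poly]
    p = p[poly]
    w = w_full[subset][poly]

    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    a = (z * w) @ z.T / w.sum()
    a = (a + a.T) / 2.0
    grm = GRM(
        matrix=a,
        ids=list(geno.individual_ids),
        n_snps=int(poly.sum()),
        weights=w,
        provenance={"label": label, "snp_subset_size": int(subset.size),
                    "weighted": weights is not None},
    )
    grm.validate()
    return grm


def exclude_regions(
    snp_meta: pd.DataFrame,
    loci: list[LocusSet],
    flank_bp: int = 50_000,
) -> np.ndarray:
    """Indices of SNPs retained after removing every lead, every proxy, and
    all SNPs within ``flank_bp`` of any of them (inclusive boundary)."""
    chrom = snp_meta["chromosome"].astype(str).to_numpy()
    bp = snp_meta["bp"].to_numpy(dtype=np.int64)
    snp_pos = {s: i for i, s in enumerate(snp_meta["snp_id"])}
    removed = np.zeros(len(snp_meta), dtype=bool)
    for ls in loci:
        for snp in ls.all_snps:
            i = snp_pos.get(snp)
            if i is None:
                continue
            removed |= (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= flank_bp)
    return np.flatnonzero(~removed)


def threshold_grm(grm: GRM, cutoff: float = 0.05) -> GRM:
    """Zero out off-diagonal genome sharing below the cutoff (strict "<"),
    leaving the diagonal untouched, so only close relatives remain."""
    a = grm.matrix.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off & (a < cutoff)] = 0.0
    out = GRM(
        matrix=a,
        ids=list(grm.ids),
        n_snps=grm.n_snps,
        weights=grm.weights,
        provenance={**grm.provenance, "threshold": cutoff},
    )
    out.validate()
    return out


def write_grm(prefix: str, grm: GRM, gz: bool = True) -> None:
    """Write in GCTA text GRM format: prefix.grm(.gz) rows of
    (i, j, n_snps, value) over the lower triangle (1-based, i >= j) plus a
    prefix.grm.id companion of (family, individual) ids."""
    opener = gzip.open if gz else open
    path = f"{prefix}.grm.gz" if gz else f"{prefix}.grm"
    with opener(path, "wt") as fh:
        n = len(grm.ids)
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps}\t{grm.matrix[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str) -> GRM:
    """Read a GCTA text GRM written by :func:`write_grm` (either .grm or
    .grm.gz). Raises on truncated triangles or id-count mismatches, naming
    the offending line."""
    ids = []
    with open(f"{prefix}.grm.id") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{prefix}.grm.id: malformed line {line!r}")
            ids.append(parts[1])
    n = len(ids)
    a = np.zeros((n, n))
    n_snps = 0
    path, opener = (f"{prefix}.grm.gz", gzip.open)
    try:
        fh = opener(path, "rt")
    except FileNotFoundError:
        path, opener = (f"{prefix}.grm", open)
        fh = opener(path, "rt")
    expected = n * (n + 1) // 2
    count = 0
    with fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed line {lineno}")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            if not (0 <= j <= i < n):
                raise ValueError(f"{path}: index out of range at line {lineno}")
            n_snps = int(parts[2])
            a[i, j] = a[j, i] = float(parts[3])
            count += 1
    if count != expected:
        raise ValueError(
            f"{path}: truncated triangle, expected {expected} rows, found {count}"
        )
    grm = GRM(matrix=a, ids=ids, n_snps=n_snps, provenance={"source": path})
    grm.validate()
    return grm
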