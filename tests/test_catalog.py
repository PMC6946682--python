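"""Association-catalog loading, counting, hydrophobicity and SNP filters,
with an exact Hardy-Weinberg test checked against a full enumeration
oracle and the chi-square approximation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaherit import (
    filter_snps,
    flag_hydrophobicity,
    hwe_test,
    load_catalog,
    summarize_catalog,
)
from metaherit.catalog import OCTANOL_LOGS


def write_catalog(tmp_path, rows, columns=None):
    columns = columns or [
        "metabolite_id", "snp_id", "chromosome", "bp", "pvalue",
        "super_class", "is_ratio",
    ]
    df = pd.DataFrame(rows, columns=columns)
    path = tmp_path / "catalog.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestLoadCatalog:
    def test_toy_file_loads_all_rows(self, tmp_path):
        path = write_catalog(
            tmp_path,
            [
                ["m1", "rs1", "1", 100, 1e-9, "lipids", 0],
                ["m1", "rs2", "1", 200, 1e-10, "lipids", 0],
                ["m2", "rs3", "2", 300, 1e-12, "organic acids", 0],
            ],
        )
        rec = load_catalog(path)
        assert len(rec) == 3
        assert rec["bp"].dtype.kind == "i"

    def test_malformed_bp_rejected_and_logged(self, tmp_path, caplog):
        path = write_catalog(
            tmp_path,
            [
                ["m1", "rs1", "1", 100, 1e-9, "lipids", 0],
                ["m1", "rs2", "1", "NA", 1e-10, "lipids", 0],
            ],
        )
        with caplog.at_level("WARNING"):
            rec = load_catalog(path)
        assert len(rec) == 1
        assert any("line 3" in m for m in caplog.messages)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = write_catalog(
            tmp_path,
            [["m1", "rs1", "1", 100]],
            columns=["metabolite_id", "snp_id", "chromosome", "bp"],
        )
        with pytest.raises(ValueError, match="pvalue"):
            load_catalog(path)

    def test_ratio_flag_from_id_convention(self, tmp_path):
        path = write_catalog(
            tmp_path,
            [["m1/m2", "rs1", "1", 100, 1e-9], ["m3", "rs2", "1", 200, 1e-9]],
            columns=["metabolite_id", "snp_id", "chromosome", "bp", "pvalue"],
        )
        rec = load_catalog(path)
        assert rec["is_ratio"].tolist() == [True, False]


class TestSummarize:
    @pytest.fixture()
    def toy(self, tmp_path):
        rows = []
        for m, sc in [("m1", "lipids"), ("m2", "organic acids")]:
            for j in range(3):
                rows.append([m, f"rs{j + 1}", "1", 100 + j, 1e-9, sc, 0])
        rows.append(["m1/m2", "rs9", "1", 900, 1e-9, None, 1])
        return load_catalog(write_catalog(tmp_path, rows))

    def test_toy_counts(self, toy):
        s = summarize_catalog(toy)
        assert s.n_unique_metabolites == 2
        assert s.n_unique_ratios == 1
        assert s.n_unique_snps <= 6 + 1
        assert s.per_super_class == {"lipids": 1, "organic acids": 1}
        assert s.n_classified == 2

    def test_row_order_invariance(self, toy):
        shuffled = toy.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a, b = summarize_catalog(toy), summarize_catalog(shuffled)
        assert a == b

    def test_raw_and_dedup_counts_reported(self, toy):
        doubled = pd.concat([toy, toy.iloc[[0]]], ignore_index=True)
        s = summarize_catalog(doubled)
        assert s.n_rows == len(toy) + 1
        assert s.n_rows_dedup == len(toy)


class TestHydrophobicity:
    def test_boundary_is_hydrophilic(self):
        # "more hydrophobic than" the reference is strict
        assert flag_hydrophobicity(OCTANOL_LOGS) == "hydrophilic"

    def test_far_below_reference_is_hydrophobic(self):
        assert flag_hydrophobicity(OCTANOL_LOGS - 5.0) == "hydrophobic"

    def test_missing_value_is_unknown(self):
        assert flag_hydrophobicity(None) == "unknown"
        assert flag_hydrophobicity(float("nan")) == "unknown"


class TestFilterSnps:
    def stats(self, **over):
        base = {"snp_id": "rs1", "maf": 0.2, "imputation_r2": 0.9, "hwe_p": 0.5}
        base.update(over)
        return base

    def test_boundaries_are_strict(self):
        rec = pd.DataFrame(
            {"metabolite_id": "m", "snp_id": [f"rs{i}" for i in range(1, 5)],
             "pvalue": 1e-9}
        )
        stats = pd.DataFrame(
            [
                self.stats(snp_id="rs1", maf=0.005),       # fails MAF
                self.stats(snp_id="rs2", imputation_r2=0.70),  # fails strict >
                self.stats(snp_id="rs3", hwe_p=1e-4),      # kept: >= alpha
                self.stats(snp_id="rs4", hwe_p=0.99e-4),   # fails strict <
            ]
        )
        out = filter_snps(rec, stats)
        assert out["snp_id"].tolist() == ["rs3"]

    def test_matches_brute_force_three_predicate_scan(self):
        rng = np.random.default_rng(6)
        snps = [f"rs{i}" for i in range(40)]
        stats = pd.DataFrame(
            {
                "snp_id": snps,
                "maf": rng.uniform(0, 0.5, 40),
                "imputation_r2": rng.uniform(0.5, 1.0, 40),
                "hwe_p": 10 ** rng.uniform(-6, 0, 40),
            }
        )
        rec = pd.DataFrame(
            {"metabolite_id": "m", "snp_id": rng.choice(snps, 100), "pvalue": 1e-9}
        )
        out = filter_snps(rec, stats)
        lookup = stats.set_index("snp_id")
        expected = [
            s for s in rec["snp_id"]
            if lookup.at[s, "maf"] > 0.01
            and lookup.at[s, "imputation_r2"] > 0.70
            and lookup.at[s, "hwe_p"] >= 1e-4
        ]
        assert out["snp_id"].tolist() == expected

    def test_absent_snps_dropped(self, caplog):
        rec = pd.DataFrame({"metabolite_id": "m", "snp_id": ["rs1", "rsX"], "pvalue": 1e-9})
        stats = pd.DataFrame([self.stats()])
        with caplog.at_level("WARNING"):
            out = filter_snps(rec, stats)
        assert out["snp_id"].tolist() == ["rs1"]


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent oracle: enumerate every heterozygote count compatible
    with the allele counts and sum probabilities <= the observed one,
    using the exact conditional formula with log factorials."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    lf = math.lgamma

    def log_prob(het):
        hom_a = (na - het) // 2
        hom_b = (nb - het) // 2
        return (
            lf(n + 1) - lf(hom_a + 1) - lf(het + 1) - lf(hom_b + 1)
            + het * math.log(2) + lf(na + 1) + lf(nb + 1) - lf(2 * n + 1)
        )

    rare = min(na, nb)
    hets = range(rare % 2, rare + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestHWE:
    @pytest.mark.parametrize(
        "counts", [(25, 50, 25), (50, 0, 50), (10, 5, 40), (3, 14, 3), (1, 1, 1)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_test(counts) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-9)

    def test_equilibrium_table_near_one(self):
        assert hwe_test((25, 50, 25)) > 0.9

    def test_strong_disequilibrium_tiny_p(self):
        assert hwe_test((50, 0, 50)) < 1e-10

    def test_monomorphic_convention(self):
        assert hwe_test((0, 0, 60)) == 1.0
        assert hwe_test((60, 0, 0)) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.integers(min_value=20, max_value=200),
        st.floats(min_value=0.2, max_value=0.8),
    )
    def test_chi2_agreement_for_large_expected_counts(self, n_pairs, freq):
        # expected counts >= 50 in every cell: exact and chi2 agree within 10%
        from scipy.stats import chi2

        n = 4 * n_pairs + 500
        n_aa = int(round(n * freq**2))
        n_bb = int(round(n * (1 - freq) ** 2))
        n_ab = n - n_aa - n_bb
        p_hat = (2 * n_aa + n_ab) / (2 * n)
        exp = np.array([n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2])
        if exp.min() < 50:
            return
        stat = float((((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum())
        approx = float(chi2.sf(stat, 1))
        exact = hwe_test((n_aa, n_ab, n_bb))
        if approx > 1e-3:  # relative agreement only meaningful off the tail
            assert exact == pytest.approx(approx, rel=0.10, abs=0.02)
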