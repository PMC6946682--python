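"""Synthetic cohort generator: pedigree structure, Mendelian genotypes,
and variance-component calibration of the metabolite generator."""

import numpy as np
import pandas as pd
import pytest

from metaherit import (
    build_grm,
    emit_catalog,
    random_architecture,
    simulate_genotypes,
    simulate_metabolites,
    simulate_pedigree,
)
from metaherit.simulate import TrueArchitecture, template_size

from conftest import MIX, TRUE_FRACTIONS


class TestPedigree:
    def test_single_mz_family_has_expected_members(self):
        ped = simulate_pedigree(1, {"mz_pair_parents": 1.0}, seed=7)
        assert len(ped) == 4
        assert ped["family_id"].nunique() == 1
        roles = sorted(ped["role"])
        assert roles == ["mz_twin_a", "mz_twin_b", "parent", "parent"]
        twins = ped[ped["role"].str.startswith("mz")]
        assert twins["father_id"].nunique() == 1 and twins["mother_id"].nunique() == 1

    def test_deterministic_for_fixed_seed(self):
        a = simulate_pedigree(50, MIX, seed=3)
        b = simulate_pedigree(50, MIX, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_follow_template_arithmetic(self):
        # largest-remainder allocation: 400 * (0.3, 0.3, 0.4) is exact
        mix = {"mz_pair_parents": 0.3, "sib_pair_parents": 0.3, "singleton": 0.4}
        ped = simulate_pedigree(400, mix, seed=1)
        assert ped["family_id"].nunique() == 400
        expected = (
            120 * template_size("mz_pair_parents")
            + 120 * template_size("sib_pair_parents")
            + 160 * template_size("singleton")
        )
        assert len(ped) == expected

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(40, MIX, seed=5)
        for _, grp in ped.groupby("family_id"):
            rows = grp.reset_index()
            for _, r in rows.iterrows():
                if pd.notna(r["father_id"]) and (rows["individual_id"] == r["father_id"]).any():
                    assert (
                        rows.index[rows["individual_id"] == r["father_id"]][0]
                        < rows.index[rows["individual_id"] == r["individual_id"]][0]
                    )

    @pytest.mark.parametrize(
        "mix", [{"mz_pair_parents": 0.5}, {"unknown_template": 1.0}]
    )
    def test_bad_mix_rejected(self, mix):
        with pytest.raises(ValueError):
            simulate_pedigree(10, mix, seed=0)


class TestGenotypes:
    def test_mz_twins_are_genotype_identical(self, cohort):
        ped, geno = cohort["ped"], cohort["geno"]
        for _, grp in ped[ped["role"].str.startswith("mz")].groupby("family_id"):
            ids = grp["individual_id"].tolist()
            ia = geno.individual_ids.index(ids[0])
            ib = geno.individual_ids.index(ids[1])
            assert np.array_equal(geno.dosages[ia], geno.dosages[ib])

    def test_first_degree_relatedness_near_half(self):
        # parent-offspring and sibling GRM entries average 0.5 at 10k SNPs
        ped = simulate_pedigree(60, {"sib_pair_parents": 1.0}, seed=21)
        geno = simulate_genotypes(ped, 10_000, seed=22)
        grm = build_grm(geno)
        idx = {s: i for i, s in enumerate(geno.individual_ids)}
        po, sib = [], []
        for _, grp in ped.groupby("family_id"):
            par = grp[grp["role"] == "parent"]["individual_id"].tolist()
            off = grp[grp["role"] == "sibling"]["individual_id"].tolist()
            for p in par:
                for o in off:
                    po.append(grm.matrix[idx[p], idx[o]])
            sib.append(grm.matrix[idx[off[0]], idx[off[1]]])
        assert abs(np.mean(po) - 0.5) < 0.05
        assert abs(np.mean(sib) - 0.5) < 0.05

    def test_block_size_one_gives_unlinked_snps(self):
        ped = simulate_pedigree(2000, {"singleton": 1.0}, seed=31)
        geno = simulate_genotypes(ped, 60, block_size=1, seed=32)
        x = geno.dosages.astype(float)
        r2 = []
        for j in range(x.shape[1] - 1):
            r = np.corrcoef(x[:, j], x[:, j + 1])[0, 1]
            r2.append(r * r)
        assert np.mean(r2) < 0.005  # E[r^2] ~ 1/n under independence

    def test_adjacent_snps_correlated_within_blocks(self, cohort):
        geno = cohort["geno"]
        x = geno.dosages[:, :20].astype(float)  # one block
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert r * r > 0.1

    def test_deterministic_and_validates(self, cohort):
        ped = cohort["ped"].head(12)
        a = simulate_genotypes(ped, 100, seed=9)
        b = simulate_genotypes(ped, 100, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        a.validate()

    def test_parameter_errors(self, cohort):
        ped = cohort["ped"].head(4)
        with pytest.raises(ValueError):
            simulate_genotypes(ped, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_genotypes(ped, 10, maf_range=(0.0, 0.5), seed=1)
        with pytest.raises(ValueError):
            simulate_genotypes(ped, 10, maf_range=(0.4, 0.6), seed=1)


class TestMetabolites:
    def test_component_variances_match_requested_fractions(self):
        ped = simulate_pedigree(1700, MIX, seed=41)  # > 5000 individuals
        geno = simulate_genotypes(ped, 800, seed=42)
        arch = random_architecture(
            geno, TRUE_FRACTIONS, n_class=4, n_notclass=4,
            min_separation_bp=300_000, seed=43,
        )
        panel = simulate_metabolites(geno, arch, ped, seed=44, keep_components=True)
        comp = panel.components["met001"]
        for name, frac in zip(
            ["background", "pedigree", "class", "notclass", "noise"], TRUE_FRACTIONS
        ):
            assert np.var(comp[name]) == pytest.approx(frac, rel=0.10)
        total = panel.values["met001"]
        assert total.var(ddof=0) == pytest.approx(1.0, rel=0.25)

    def test_pure_noise_uncorrelated_with_causal_dosage(self, cohort):
        geno, ped = cohort["geno"], cohort["ped"]
        arch = random_architecture(geno, (0, 0, 0, 0, 1.0), n_class=3, n_notclass=3, seed=5)
        panel = simulate_metabolites(geno, arch, ped, seed=6)
        y = panel.values["met001"].to_numpy()
        for j in arch.class_loci:
            r = np.corrcoef(y, geno.dosages[:, j])[0, 1]
            assert abs(r) < 4 / np.sqrt(len(y))

    def test_lod_censoring_flags_expected_fraction(self, cohort):
        geno, ped, arch = cohort["geno"], cohort["ped"], cohort["arch"]
        panel = simulate_metabolites(geno, arch, ped, lod_quantile=0.05, seed=8)
        frac = panel.below_lod["met001"].mean()
        assert frac == pytest.approx(0.05, abs=0.01)
        # censored entries are unobserved
        assert panel.values["met001"][panel.below_lod["met001"]].isna().all()

    def test_missing_at_random_rate(self, cohort):
        geno, ped, arch = cohort["geno"], cohort["ped"], cohort["arch"]
        panel = simulate_metabolites(geno, arch, ped, missing_rate=0.10, seed=9)
        assert panel.values["met001"].isna().mean() == pytest.approx(0.10, abs=0.03)

    def test_invalid_fractions_rejected(self, cohort):
        geno = cohort["geno"]
        with pytest.raises(ValueError):
            TrueArchitecture(
                class_loci=np.array([0]), notclass_loci=np.array([1]),
                background_snps=np.array([2]), class_effects=np.array([1.0]),
                notclass_effects=np.array([1.0]), background_effects=np.array([1.0]),
                var_fractions=(0.5, 0.2, 0.1, 0.1, 0.2),
            ).validate()

    def test_architecture_snp_sets_disjoint(self, cohort):
        arch = cohort["arch"]
        assert not (set(arch.class_loci) & set(arch.notclass_loci))
        assert not (set(arch.class_loci) & set(arch.background_snps))
        assert not (set(arch.notclass_loci) & set(arch.background_snps))


class TestEmitCatalog:
    def test_one_record_per_causal_locus(self, cohort):
        geno = cohort["geno"]
        arch = random_architecture(
            geno, TRUE_FRACTIONS, n_class=5, n_notclass=3, seed=17
        )
        cat = emit_catalog(arch, geno.snp_meta)
        assert len(cat) == 8
        assert (cat["pvalue"] < 5e-8).all()
        assert set(cat["super_class"]) == {"lipids", "organic acids"}

    def test_empty_architecture_gives_empty_table(self, cohort):
        geno = cohort["geno"]
        arch = TrueArchitecture(
            class_loci=np.array([], dtype=int), notclass_loci=np.array([], dtype=int),
            background_snps=np.array([0]), class_effects=np.array([]),
            notclass_effects=np.array([]), background_effects=np.array([1.0]),
            var_fractions=(0.3, 0, 0, 0, 0.7),
        )
        cat = emit_catalog(arch, geno.snp_meta)
        assert len(cat) == 0
        assert "snp_id" in cat.columns
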