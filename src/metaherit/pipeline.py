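"""End-to-end orchestration: catalog -> clumping -> GRMs -> preprocessing ->
per-metabolite GREML -> meta-regression, with a manifest of every decision.

Every tunable defaults to the analysis' standard value (clump r^2 0.10 in a
500 kb radius, 50 kb locus flank, 0.05 genome-sharing cutoff, 25% CV and 5%
missing-rate QC bounds, 5 SD outlier masking, 10,000 Monte-Carlo draws).
The pipeline can run on files (PLINK genotypes, tab-delimited catalog and
panel) or generate a fully synthetic cohort with known truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from metaherit import io as mio
from metaherit.catalog import compute_snp_stats, filter_snps, load_catalog
from metaherit.clumping import build_class_locus_sets, unrelated_subset, write_locus_set
from metaherit.grm import (
    build_grm,
    compute_ld_weights,
    exclude_regions,
    threshold_grm,
    write_grm,
)
from metaherit.metareg import build_dependence_matrix, fdr_adjust, fit_meta, robust_moderator_test
from metaherit.preprocess import (
    impute_below_lod,
    impute_chained,
    mask_outliers,
    qc_filter,
    transform,
)
from metaherit.reml import (
    composite_heritabilities,
    fit_reml,
    lrt_reduced,
    mc_standard_errors,
)
from metaherit.simulate import (
    emit_catalog,
    random_architecture,
    simulate_genotypes,
    simulate_metabolites,
    simulate_pedigree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "compare_covariate_models",
    "recovery_replicate",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the standard analysis
    values. Either ``genotypes_prefix``/``catalog_path``/``panel_path`` or
    a ``simulate`` block must be provided."""

    output_dir: str = "results"
    genotypes_prefix: str | None = None
    catalog_path: str | None = None
    panel_path: str | None = None
    covariates_path: str | None = None
    simulate: dict | None = None
    super_class: str = "lipids"
    clump_r2: float = 0.10
    clump_radius_bp: int = 500_000
    max_unrelated: int = 2500
    ld_window_bp: int = 100_000
    flank_bp: int = 50_000
    grm_cutoff: float = 0.05
    maf_min: float = 0.01
    r2_min: float = 0.70
    hwe_alpha: float = 1e-4
    cv_max: float = 0.25
    miss_max: float = 0.05
    outlier_sd: float = 5.0
    mc_draws: int = 10_000
    transform_map: dict = field(
        default_factory=lambda: {"nmr": "inverse_normal", "ms": "natural_log"}
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@contextmanager
def _stage(name: str):
    logger.info("pipeline stage: %s", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def _default_simulation(seed: int) -> dict:
    return {
        "n_families": 300,
        "family_mix": {"mz_pair_parents": 0.3, "sib_pair_parents": 0.3, "singleton": 0.4},
        "n_snps": 2000,
        "block_size": 20,
        "maf_range": [0.05, 0.5],
        "n_metabolites": 12,
        "var_fractions": [0.30, 0.15, 0.06, 0.02, 0.47],
        "n_class": 5,
        "n_notclass": 5,
        "lod_quantile": 0.02,
        "missing_rate": 0.01,
        "seed": seed,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the results directory.

    Writes locus sets, the four GRMs, the QC report, a per-metabolite
    heritability table, the meta-regression table, and a JSON manifest
    (package/library versions, seeds, parameter values and a convergence
    summary). Any stage failure halts with a stage-tagged error; outputs
    written so far are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "metaherit": "0.1.0",
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "derived_seeds": seeds,
    }
    truth = None

    with _stage("inputs"):
        if config.simulate is not None:
            sim = {**_default_simulation(seeds[0]), **config.simulate}
            ped = simulate_pedigree(sim["n_families"], sim["family_mix"], seed=sim["seed"])
            geno = simulate_genotypes(
                ped, sim["n_snps"], block_size=sim["block_size"],
                maf_range=tuple(sim["maf_range"]), seed=sim["seed"] + 1,
            )
            archs = [
                random_architecture(
                    geno, tuple(sim["var_fractions"]), n_class=sim["n_class"],
                    n_notclass=sim["n_notclass"], flank_bp=config.flank_bp,
                    seed=sim["seed"] + 2 + k,
                )
                for k in range(sim["n_metabolites"])
            ]
            covars = pd.DataFrame(
                {
                    "sex": ped["sex"].to_numpy(dtype=float),
                    "age": np.round(
                        np.random.default_rng(sim["seed"] + 99).uniform(18, 80, len(ped)), 1
                    ),
                },
                index=ped["individual_id"],
            )
            panel = simulate_metabolites(
                geno, archs, ped, covars=covars,
                covar_effects={"sex": 0.2, "age": 0.005},
                lod_quantile=sim["lod_quantile"], missing_rate=sim["missing_rate"],
                seed=sim["seed"] + 50, location=10.0,
            )
            catalog = emit_catalog(archs, geno.snp_meta, seed=sim["seed"] + 60)
            catalog_path = out / "catalog.tsv"
            catalog.to_csv(catalog_path, sep="\t", index=False, na_rep="NA")
            catalog = load_catalog(catalog_path)
            truth = {
                "var_fractions": sim["var_fractions"],
                "class_loci": [a.class_loci.tolist() for a in archs],
                "notclass_loci": [a.notclass_loci.tolist() for a in archs],
            }
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
            mio.write_plink(str(out / "genotypes"), geno, ped)
        else:
            for fld in ("genotypes_prefix", "catalog_path", "panel_path"):
                if getattr(config, fld) is None:
                    raise ValueError(f"config field '{fld}' is required when not simulating")
            geno = mio.read_plink(config.genotypes_prefix)
            fam = pd.read_csv(
                f"{config.genotypes_prefix}.fam", sep=r"\s+", header=None,
                names=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
                dtype=str,
            )
            fam["father_id"] = fam["father_id"].replace("0", np.nan)
            fam["mother_id"] = fam["mother_id"].replace("0", np.nan)
            fam["sex"] = fam["sex"].astype(int)
            fam["role"] = np.where(fam["father_id"].isna(), "singleton", "sibling")
            ped = fam[["individual_id", "family_id", "father_id", "mother_id", "sex", "role"]]
            catalog = load_catalog(config.catalog_path)
            values = mio.read_panel_tsv(config.panel_path)
            from metaherit.simulate import MetabolitePanel

            panel = MetabolitePanel(
                values=values,
                below_lod=pd.DataFrame(False, index=values.index, columns=values.columns),
                lod=pd.Series(np.nan, index=values.columns),
                batch=pd.Series("b1", index=values.index),
                platform=pd.Series("nmr", index=values.columns),
                class_label=pd.Series(config.super_class, index=values.columns),
            )
            covars = (
                mio.read_panel_tsv(config.covariates_path)
                if config.covariates_path
                else pd.DataFrame(index=values.index)
            )

    with _stage("snp_filters"):
        stats = compute_snp_stats(geno)
        catalog_f = filter_snps(
            catalog, stats, maf_min=config.maf_min, r2_min=config.r2_min,
            hwe_alpha=config.hwe_alpha,
        )
        manifest["n_catalog_rows"] = int(len(catalog))
        manifest["n_catalog_rows_after_snp_filters"] = int(len(catalog_f))

    with _stage("clumping"):
        unrel = unrelated_subset(ped, config.max_unrelated)
        class_set, notclass_set = build_class_locus_sets(
            catalog_f, config.super_class, geno,
            r2_threshold=config.clump_r2, radius_bp=config.clump_radius_bp,
            ld_individuals=unrel,
        )
        write_locus_set(str(out / "loci_class"), class_set)
        write_locus_set(str(out / "loci_notclass"), notclass_set)
        manifest["n_class_leads"] = len(class_set.leads)
        manifest["n_notclass_leads"] = len(notclass_set.leads)

    with _stage("grms"):
        weights = compute_ld_weights(geno, window_bp=config.ld_window_bp)
        snp_idx = {s: j for j, s in enumerate(geno.snp_meta["snp_id"])}
        keep = exclude_regions(geno.snp_meta, [class_set, notclass_set], config.flank_bp)
        grm1 = build_grm(geno, keep, weights, label="G1_genomewide_minus_loci")
        grm2 = threshold_grm(
            build_grm(geno, None, weights, label="G2_pedigree"), config.grm_cutoff
        )
        class_cols = np.array([snp_idx[s] for s in class_set.leads], dtype=int)
        notclass_cols = np.array([snp_idx[s] for s in notclass_set.leads], dtype=int)
        grm3 = build_grm(geno, class_cols, weights, label="G3_class_hits")
        grm4 = build_grm(geno, notclass_cols, weights, label="G4_notclass_hits")
        for name, g in [("grm1", grm1), ("grm2", grm2), ("grm3", grm3), ("grm4", grm4)]:
            write_grm(str(out / name), g)

    with _stage("preprocessing"):
        qc_panel, report = qc_filter(panel, cv_max=config.cv_max, miss_max=config.miss_max)
        values = qc_panel.values.copy()
        for m in values.columns:
            values[m] = mask_outliers(values[m], k=config.outlier_sd)
            report.table.loc[m, "n_outliers_masked"] = int(
                qc_panel.values[m].notna().sum() - values[m].notna().sum()
            )
            values[m] = impute_below_lod(values[m], qc_panel.below_lod[m], qc_panel.lod[m])
        values, n_imp = impute_chained(values, covars=None, seed=seeds[1])
        for m in values.columns:
            method = config.transform_map.get(str(qc_panel.platform[m]), "inverse_normal")
            if method == "natural_log" and (values[m] <= 0).any():
                method = "inverse_normal"  # log undefined for simulated negative levels
            values[m] = transform(values[m], method=method)
            report.table.loc[m, "transform"] = method
        report.table["n_chained_imputed"] = n_imp
        report.table.to_csv(out / "qc_report.tsv", sep="\t", na_rep="NA")

    with _stage("greml"):
        x_cols = [np.ones(len(ped))]
        names = ["intercept"]
        for col in getattr(covars, "columns", []):
            x_cols.append(covars[col].to_numpy(dtype=float))
            names.append(col)
        batch_d = pd.get_dummies(panel.batch, drop_first=True)
        for col in batch_d.columns:
            x_cols.append(batch_d[col].to_numpy(dtype=float))
            names.append(f"batch_{col}")
        x = np.column_stack(x_cols)
        grms = [grm1, grm2, grm3, grm4]
        rows = []
        counts = {"converged": 0, "non_converged": 0, "non_invertible": 0}
        for m in values.columns:
            y = values[m].to_numpy(dtype=float)
            try:
                fit = fit_reml(y, x, grms)
            except np.linalg.LinAlgError:
                counts["non_invertible"] += 1
                continue
            counts["converged" if fit.converged else "non_converged"] += 1
            h2 = composite_heritabilities(fit)
            ses = mc_standard_errors(fit, n_draws=config.mc_draws, seed=seeds[2])
            lrt3 = lrt_reduced(y, x, grms, fit, drop=["V(G3)"])
            lrt4 = lrt_reduced(y, x, grms, fit, drop=["V(G4)"])
            lrt34 = lrt_reduced(y, x, grms, fit, drop=["V(G3)", "V(G4)"])
            row = {
                "metabolite_id": m,
                "super_class": panel.class_label[m],
                "platform": panel.platform[m],
                **{n: v for n, v in zip(fit.component_names, fit.estimates)},
                "Vp": fit.Vp,
                **h2.as_dict(),
                **{f"se_{k}": v for k, v in ses.items()},
                "loglik": fit.loglik,
                "converged": fit.converged,
                "bent": fit.bent,
                "n_iter": fit.n_iter,
                "lrt_class_stat": lrt3.statistic,
                "lrt_class_p": lrt3.pvalue,
                "lrt_notclass_stat": lrt4.statistic,
                "lrt_notclass_p": lrt4.pvalue,
                "lrt_both_stat": lrt34.statistic,
                "lrt_both_p": lrt34.pvalue,
            }
            rows.append(row)
        herit = pd.DataFrame(rows)
        herit.to_csv(out / "heritability.tsv", sep="\t", index=False, na_rep="NA",
                     float_format="%.10g")
        manifest["convergence"] = counts

    with _stage("meta_regression"):
        meta_rows = []
        if len(herit) >= 3:
            n_i = panel.values[herit["metabolite_id"]].notna().sum(axis=0).to_numpy(float)
            obs = panel.values[herit["metabolite_id"]].notna().to_numpy()
            overlap = obs.T.astype(float) @ obs
            corr = (
                panel.values[herit["metabolite_id"]]
                .corr(method="spearman")
                .fillna(0.0)
                .to_numpy()
            )
            np.fill_diagonal(corr, 1.0)
            dep = build_dependence_matrix(n_i, overlap, corr)
            classes = herit["super_class"].astype(str)
            moderator_cols = pd.get_dummies(classes, drop_first=True).astype(float)
            if moderator_cols.shape[1] >= 1:
                design = np.column_stack([np.ones(len(herit)), moderator_cols.to_numpy()])
                for target in ["h2_total", "h2_metabolite_hits", "h2_class_hits",
                               "h2_notclass_hits"]:
                    ses = herit[f"se_{target}"].to_numpy(float)
                    ses = np.where(ses > 0, ses, 1e-6)
                    res = fit_meta(herit[target].to_numpy(float), ses, design, dep,
                                   cluster_ids=herit["metabolite_id"].to_numpy())
                    fstat, df1, df2, p = robust_moderator_test(
                        res, herit["metabolite_id"].to_numpy()
                    )
                    meta_rows.append(
                        {"outcome": target, "F": fstat, "df1": df1, "df2": df2,
                         "p": p, "tau2": res.tau2}
                    )
        meta = pd.DataFrame(meta_rows)
        if len(meta):
            meta["fdr_p"] = fdr_adjust(meta["p"].to_numpy())
        meta.to_csv(out / "meta_regression.tsv", sep="\t", index=False, na_rep="NA")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def recovery_replicate(
    seed: int,
    n_families: int = 340,
    family_mix: dict | None = None,
    n_snps: int = 4000,
    var_fractions: tuple = (0.30, 0.15, 0.06, 0.02, 0.47),
    n_class: int = 8,
    n_notclass: int = 8,
):
    """One full simulate -> curate -> clump -> GRM -> GREML replicate.

    Generates a twin-family cohort with a known four-component architecture,
    rebuilds the locus sets from the emitted catalog by clumping, constructs
    the four LD-weighted GRMs, and fits the unconstrained four-component
    model. Returns (HeritabilityEstimate, VarianceModelFit). The default
    family mix of MZ-pair, sibling-pair and singleton families yields about
    1200 genotyped individuals at 340 families.
    """
    if family_mix is None:
        family_mix = {"mz_pair_parents": 0.35, "sib_pair_parents": 0.35,
                      "singleton": 0.30}
    ped = simulate_pedigree(n_families, family_mix, seed=seed)
    geno = simulate_genotypes(ped, n_snps, seed=seed + 1)
    arch = random_architecture(
        geno, var_fractions, n_class=n_class, n_notclass=n_notclass, seed=seed + 2
    )
    panel = simulate_metabolites(geno, arch, ped, seed=seed + 3)
    y = panel.values["met001"].to_numpy()

    weights = compute_ld_weights(geno)
    catalog = emit_catalog(arch, geno.snp_meta, seed=seed + 4)
    cs, ns = build_class_locus_sets(
        catalog, "lipids", geno, ld_individuals=unrelated_subset(ped)
    )
    keep = exclude_regions(geno.snp_meta, [cs, ns])
    snp_idx = {s: j for j, s in enumerate(geno.snp_meta["snp_id"])}
    grms = [
        build_grm(geno, keep, weights),
        threshold_grm(build_grm(geno, None, weights), 0.05),
        build_grm(geno, np.array([snp_idx[s] for s in cs.leads]), weights),
        build_grm(geno, np.array([snp_idx[s] for s in ns.leads]), weights),
    ]
    fit = fit_reml(y, None, grms)
    return composite_heritabilities(fit), fit


def compare_covariate_models(
    values: pd.DataFrame,
    covars: pd.DataFrame,
    grms,
    model_specs: dict[str, list[str]],
) -> pd.DataFrame:
    """Compare covariate models per metabolite and pick the most
    parsimonious by AIC.

    The variance structure is estimated once per metabolite under the union
    of all covariates; each candidate spec is then evaluated by its
    Gaussian (ML) log-likelihood at that fixed structure with GLS fixed
    effects, and AIC = 2 * n_covariates - 2 * loglik. At a fixed variance
    structure, adding covariates can only raise the log-likelihood, so the
    AIC penalty is what arbitrates.
    """
    if len(model_specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    all_cols: list[str] = []
    for cols in model_specs.values():
        for c in cols:
            if c not in all_cols:
                all_cols.append(c)
    missing = [c for c in all_cols if c not in covars.columns]
    if missing:
        raise ValueError(f"covariate columns not found: {missing}")

    n = len(covars)
    from metaherit.reml import _as_matrices, _assemble_v, _invert_v

    mats = _as_matrices(grms)
    rows = []
    for m in values.columns:
        y = values[m].to_numpy(dtype=float)
        x_full = np.column_stack([np.ones(n)] + [covars[c].to_numpy(float) for c in all_cols])
        fit = fit_reml(y, x_full, grms)
        v = _assemble_v(fit.estimates, mats, n)
        vinv, logdet, _ = _invert_v(v, bend=True)
        for name, cols in model_specs.items():
            x = np.column_stack([np.ones(n)] + [covars[c].to_numpy(float) for c in cols])
            xtvx = x.T @ vinv @ x
            beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
            resid = y - x @ beta
            ll = -0.5 * (n * np.log(2 * np.pi) + logdet + float(resid @ vinv @ resid))
            rows.append(
                {"metabolite_id": m, "model": name, "n_covariates": len(cols),
                 "loglik": ll, "aic": 2 * (len(cols) + 1) - 2 * ll}
            )
    table = pd.DataFrame(rows)
    chosen = table.loc[table.groupby("metabolite_id")["aic"].idxmin(), ["metabolite_id", "model"]]
    table = table.merge(chosen.rename(columns={"model": "chosen"}), on="metabolite_id")
    table["selected"] = table["model"] == table["chosen"]
    return table.drop(columns=["chosen"])
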