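"""Metabolite panel preprocessing: QC, censoring, imputation, transform.

Simulates a panel with below-detection-limit censoring and random
missingness, then runs the preprocessing chain: CV/missing-rate QC ->
5 SD outlier masking -> LOD/2 imputation -> chained imputation of the
remaining missing values -> inverse-normal rank transform.
"""

import numpy as np

from metaherit import (
    impute_below_lod,
    impute_chained,
    mask_outliers,
    qc_filter,
    random_architecture,
    simulate_genotypes,
    simulate_metabolites,
    simulate_pedigree,
    transform,
)

ped = simulate_pedigree(150, seed=1)
geno = simulate_genotypes(ped, 500, seed=2)
archs = [
    random_architecture(geno, (0.3, 0.15, 0.06, 0.02, 0.47),
                        min_separation_bp=200_000, seed=3 + k)
    for k in range(4)
]
panel = simulate_metabolites(
    geno, archs, ped, lod_quantile=0.05, missing_rate=0.02, seed=9, location=10.0
)
print(f"raw panel: {panel.values.shape[1]} metabolites, "
      f"{int(panel.below_lod.to_numpy().sum())} below-LOD entries, "
      f"{int(panel.values.isna().to_numpy().sum())} unobserved values")

qc_panel, report = qc_filter(panel)
print(f"QC: {len(report.retained())}/{panel.values.shape[1]} retained "
      f"(CV <= 25%, missing <= 5%)")

values = qc_panel.values.copy()
for m in values.columns:
    values[m] = mask_outliers(values[m], k=5)
    values[m] = impute_below_lod(values[m], qc_panel.below_lod[m], qc_panel.lod[m])
values, n_imputed = impute_chained(values, seed=7)
print(f"chained imputation filled {n_imputed} remaining value(s)")

for m in values.columns:
    values[m] = transform(values[m], "inverse_normal")
print("\nafter inverse-normal transform (mean ~ 0, SD ~ 1 by construction):")
print(values.describe().loc[["mean", "std"]].round(3).to_string())
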