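"""Metabolite panel quality control, imputation and normalization.

Pipeline order (fixed and logged by the pipeline module): QC filter ->
outlier masking -> below-detection-limit imputation -> chained imputation
of remaining missing values -> normalizing transform. Metabolites measured
by NMR-style platforms are inverse-normal rank transformed; MS-style
platforms use the natural logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from metaherit.simulate import MetabolitePanel

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "impute_below_lod",
    "impute_chained",
    "mask_outliers",
    "qc_filter",
    "transform",
]


@dataclass
class QCReport:
    """Per-metabolite QC bookkeeping; retained iff CV <= cv_max and
    missing rate <= miss_max (both bounds strict on exclusion)."""

    table: pd.DataFrame  # columns: cv, missing_rate, retained, and counters

    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def _cv_per_metabolite(values: pd.DataFrame, batch: pd.Series) -> pd.Series:
    """Coefficient of variation (SD/mean of raw values) per metabolite per
    batch, averaged over batches. Batches with nonpositive mean propagate
    NaN and are ignored in the average."""
    cvs = {}
    for m in values.columns:
        per_batch = []
        for _, idx in values.groupby(batch).groups.items():
            v = values.loc[idx, m].dropna()
            if len(v) < 2 or v.mean() == 0:
                continue
            per_batch.append(v.std(ddof=1) / abs(v.mean()))
        cvs[m] = float(np.mean(per_batch)) if per_batch else np.nan
    return pd.Series(cvs)


def qc_filter(
    panel: MetabolitePanel,
    cv_max: float = 0.25,
    miss_max: float = 0.05,
    cv: pd.Series | None = None,
) -> tuple[MetabolitePanel, QCReport]:
    """Drop metabolites whose mean coefficient of variation exceeds
    ``cv_max`` or whose missing rate exceeds ``miss_max`` (strict ">").

    CV is computed per batch from the raw values unless supplied. Entries
    censored below the detection limit are measurements (recoverable by
    LOD/2 imputation), so they do not count toward the missing rate.
    """
    values = panel.values
    if cv is None:
        cv = _cv_per_metabolite(values, panel.batch)
    miss = (values.isna() & ~panel.below_lod).mean(axis=0)
    retained = ~((cv > cv_max) | (miss > miss_max))
    report = QCReport(
        pd.DataFrame(
            {
                "cv": cv,
                "missing_rate": miss,
                "retained": retained,
                "n_below_lod": panel.below_lod.sum(axis=0),
                "n_outliers_masked": 0,
                "n_chained_imputed": 0,
                "transform": "",
            }
        )
    )
    keep = report.retained()
    out = MetabolitePanel(
        values=values[keep].copy(),
        below_lod=panel.below_lod[keep].copy(),
        lod=panel.lod[keep].copy(),
        batch=panel.batch,
        platform=panel.platform[keep].copy(),
        class_label=panel.class_label[keep].copy(),
    )
    return out, report


def mask_outliers(values: pd.Series | np.ndarray, k: float = 5.0):
    """Set values more than ``k`` standard deviations from the mean (of the
    non-missing values) to missing, in a single pass."""
    ser = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = ser.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    mu, sd = obs.mean(), obs.std(ddof=1)
    out = ser.copy()
    if sd > 0:
        mask = (ser - mu).abs() > k * sd
        out[mask] = np.nan
    return out if isinstance(values, pd.Series) else out.to_numpy()


def impute_below_lod(
    values: pd.Series,
    below_lod: pd.Series,
    lod: float | None = None,
) -> pd.Series:
    """Impute censored entries with half the detection limit, or half the
    lowest observed level when the limit is unknown."""
    out = values.copy()
    flagged = below_lod.astype(bool)
    if not flagged.any():
        return out
    if lod is not None and np.isfinite(lod):
        fill = lod / 2.0
    else:
        observed = values[~flagged].dropna()
        if observed.empty:
            raise ValueError("all values below detection limit and limit unknown")
        fill = observed.min() / 2.0
    out[flagged] = fill
    return out


def impute_chained(
    panel_values: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    max_iter: int = 20,
    tol: float = 1e-4,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Multivariate imputation by chained equations with deterministic
    regression-mean draws.

    Each metabolite with missing entries is regressed (least squares, with
    intercept) on all other metabolites and covariates using the current
    completed data; its missing entries are replaced by the predictions.
    Iterate until the largest absolute change is below ``tol`` or
    ``max_iter`` sweeps; non-convergence warns and returns the last
    iterate. The seed fixes the metabolite visiting order.

    Returns the completed panel and the number of values imputed.
    """
    x = panel_values.copy().astype(float)
    miss = x.isna()
    n_imputed = int(miss.to_numpy().sum())
    if n_imputed == 0:
        return x, 0
    # start from column means
    x = x.fillna(x.mean())
    rng = np.random.default_rng(seed)
    order = list(panel_values.columns[miss.any(axis=0)])
    rng.shuffle(order)

    cov = covars.to_numpy(dtype=float) if covars is not None else np.empty((len(x), 0))
    for _ in range(max_iter):
        delta = 0.0
        for m in order:
            others = x.drop(columns=[m]).to_numpy()
            design = np.column_stack([np.ones(len(x)), others, cov])
            rows_obs = ~miss[m].to_numpy()
            beta, *_ = np.linalg.lstsq(design[rows_obs], x.loc[rows_obs, m].to_numpy(), rcond=None)
            pred = design[~rows_obs] @ beta
            old = x.loc[~rows_obs, m].to_numpy()
            delta = max(delta, float(np.max(np.abs(pred - old))) if pred.size else 0.0)
            x.loc[~rows_obs, m] = pred
        if delta < tol:
            break
    else:
        logger.warning("impute_chained: no convergence after %d iterations (delta=%g)",
                       max_iter, delta)
    return x, n_imputed


def transform(values: pd.Series | np.ndarray, method: str = "inverse_normal"):
    """Normalize a metabolite: ``inverse_normal`` maps Blom-offset ranks
    through the standard normal quantile function,
    Phi^-1((rank - 3/8) / (n + 1/4)), with average ranks for ties;
    ``natural_log`` takes ln(x) and requires strictly positive values.
    Missing entries pass through unchanged."""
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    if method == "inverse_normal":
        ranks = rankdata(arr[obs], method="average")
        n = obs.sum()
        out[obs] = norm.ppf((ranks - 0.375) / (n + 0.25))
    elif method == "natural_log":
        if (arr[obs] <= 0).any():
            raise ValueError("natural_log requires strictly positive values")
        out[obs] = np.log(arr[obs])
    else:
        raise ValueError(f"unknown transform method: {method}")
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
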