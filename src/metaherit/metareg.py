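"""Dependence-weighted mixed-effect meta-regression of heritability.

Tests whether per-metabolite heritability estimates are moderated by
metabolite class and platform. Because metabolites are measured on
overlapping participants and are phenotypically correlated, the estimates
are dependent; the dependence matrix carries each metabolite's sample
size on the diagonal and N12 / sqrt(n1 * n2) * r off-diagonal (N12 the
sample overlap, r the cross-metabolite rank correlation). The model is

    b_i = x_i' beta + u_i + eps_i,  cov(u) = tau2 * R,  var(eps_i) = se_i^2

with R the dependence matrix scaled to unit diagonal, tau2 estimated by
REML, and cluster-robust (sandwich) inference on the moderator block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MetaRegressionResult",
    "build_dependence_matrix",
    "fdr_adjust",
    "fit_meta",
    "robust_moderator_test",
]


@dataclass
class MetaRegressionResult:
    coefficients: np.ndarray
    coef_names: list[str]
    tau2: float
    loglik: float
    vcov: np.ndarray  # model-based covariance of beta
    residuals: np.ndarray
    design: np.ndarray
    marginal_vinv: np.ndarray
    cluster_ids: np.ndarray | None = None
    robust: dict = field(default_factory=dict)


def build_dependence_matrix(n: np.ndarray, overlap: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Dependence matrix with sample sizes on the diagonal and
    N12 / sqrt(n1 * n2) * r off-diagonal; exact symmetry enforced."""
    n = np.asarray(n, dtype=float)
    overlap = np.asarray(overlap, dtype=float)
    corr = np.asarray(corr, dtype=float)
    k = n.size
    if overlap.shape != (k, k) or corr.shape != (k, k):
        raise ValueError("overlap and corr must be k x k")
    if (np.abs(corr) > 1 + 1e-12).any():
        raise ValueError("correlations must lie in [-1, 1]")
    pairwise_min = np.minimum.outer(n, n)
    if (overlap > pairwise_min + 1e-9).any():
        raise ValueError("sample overlap cannot exceed the smaller sample size")
    d = overlap / np.sqrt(np.outer(n, n)) * corr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, n)
    return d


def _normalize_to_correlation(dep: np.ndarray) -> np.ndarray:
    """Scale the dependence matrix to unit diagonal; project to the nearest
    positive semidefinite matrix (eigenvalue clipping) if needed."""
    diag = np.diag(dep).copy()
    if (diag <= 0).any():
        raise ValueError("dependence matrix diagonal must be positive")
    r = dep / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(r, 1.0)
    w = np.linalg.eigvalsh(r)
    if w.min() < -1e-10:
        logger.warning("dependence matrix not PSD; projecting negative eigenvalues")
        w, u = np.linalg.eigh(r)
        r = (u * np.clip(w, 0, None)) @ u.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


def _profile_reml_nll(tau2, b, x, r, se2):
    v = tau2 * r + np.diag(se2)
    try:
        c = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, x.T @ vinv @ b)
    resid = b - x @ beta
    return 0.5 * (logdet_v + logdet_xtvx + float(resid @ vinv @ resid))


def fit_meta(
    estimates,
    ses,
    moderators,
    dependence: np.ndarray | None = None,
    cluster_ids=None,
    normalize: bool = True,
    tau2: float | None = None,
    coef_names: list[str] | None = None,
) -> MetaRegressionResult:
    """REML mixed-effect meta-regression with a dependence random factor.

    ``moderators`` is the design matrix (include the intercept column);
    ``dependence`` the combined overlap/correlation matrix (defaults to
    independence); ``normalize`` rescales it to unit diagonal before use as
    the random-effect correlation structure (the raw mode is retained for
    sensitivity analysis). ``tau2`` may be fixed (e.g. 0 reduces the model
    to weighted least squares with weights 1/se^2 when R is diagonal).
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    x = np.asarray(moderators, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("moderator design is rank deficient after coding")
    k = b.size
    if dependence is None:
        r = np.eye(k)
    else:
        r = _normalize_to_correlation(dependence) if normalize else np.asarray(dependence, float)
    se2 = se**2

    if tau2 is None:
        upper = max(10.0 * float(np.var(b)), 10.0 * se2.max(), 1e-6)
        res = optimize.minimize_scalar(
            _profile_reml_nll, bounds=(0.0, upper), args=(b, x, r, se2), method="bounded",
            options={"xatol": 1e-12},
        )
        tau2_hat = float(res.x)
        # the boundary tau2 = 0 is a legal REML solution; prefer it when flat
        if _profile_reml_nll(0.0, b, x, r, se2) <= res.fun + 1e-10:
            tau2_hat = 0.0
    else:
        tau2_hat = float(tau2)

    v = tau2_hat * r + np.diag(se2)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ (x.T @ vinv @ b)
    resid = b - x @ beta
    nll = _profile_reml_nll(tau2_hat, b, x, r, se2)
    if coef_names is None:
        coef_names = [f"b{j}" for j in range(x.shape[1])]
    return MetaRegressionResult(
        coefficients=beta,
        coef_names=list(coef_names),
        tau2=tau2_hat,
        loglik=-float(nll) - 0.5 * (k - x.shape[1]) * np.log(2 * np.pi),
        vcov=xtvx_inv,
        residuals=resid,
        design=x,
        marginal_vinv=vinv,
        cluster_ids=None if cluster_ids is None else np.asarray(cluster_ids),
    )


def _sym_power(a: np.ndarray, power: float, eps: float = 1e-10) -> np.ndarray:
    w, u = np.linalg.eigh((a + a.T) / 2.0)
    w = np.clip(w, eps * max(abs(w).max(), 1.0), None)
    return (u * w**power) @ u.T


def robust_moderator_test(
    result: MetaRegressionResult,
    cluster_ids=None,
    coef_idx=None,
    method: str = "cr2",
) -> tuple[float, float, float, float]:
    """Cluster-robust Wald F test of a block of moderator coefficients.

    ``method="cr2"`` (default) applies the bias-reducing CR2 cluster
    adjustment under the fitted marginal covariance as working model and
    refers the Wald statistic to an F distribution with
    Satterthwaite-style (approximate Hotelling) denominator degrees of
    freedom — the calibrated choice when few clusters inform a
    coefficient. ``method="cr1"`` is the conventional sandwich with meat
    scaled by m/(m-p) and df2 = m - p (m clusters, p coefficients), as in
    standard meta-regression software. Requires more clusters than
    coefficients; default block: all non-intercept coefficients.
    """
    ids = result.cluster_ids if cluster_ids is None else np.asarray(cluster_ids)
    if ids is None:
        raise ValueError("cluster ids are required for the robust test")
    x, vinv, resid = result.design, result.marginal_vinv, result.residuals
    n, p = x.shape
    clusters = np.unique(ids)
    m = clusters.size
    if m <= p:
        raise ValueError("need more clusters than coefficients for robust inference")

    if coef_idx is None:
        coef_idx = list(range(1, p))
    coef_idx = list(coef_idx)
    q = len(coef_idx)
    if q == 0:
        raise ValueError("no coefficients selected for the moderator test")

    bread = np.linalg.inv(x.T @ vinv @ x)
    u_mat = vinv @ x  # weighted design
    row_sets = [np.flatnonzero(ids == c) for c in clusters]

    if method == "cr1":
        meat = np.zeros((p, p))
        wr = vinv @ resid
        for rows in row_sets:
            g = x[rows].T @ wr[rows]
            meat += np.outer(g, g)
        meat *= m / (m - p)
        vc = bread @ meat @ bread
        vc = (vc + vc.T) / 2.0
        bsel = result.coefficients[coef_idx]
        vsel = vc[np.ix_(coef_idx, coef_idx)]
        stat = float(bsel @ np.linalg.solve(vsel, bsel)) / q
        df2 = float(m - p)
        pval = float(f_dist.sf(stat, q, df2))
        result.robust = {"F": stat, "df1": q, "df2": df2, "p": pval, "vcov": vc,
                         "method": method}
        return stat, float(q), df2, pval
    if method != "cr2":
        raise ValueError("method must be 'cr2' or 'cr1'")

    # working covariance: the fitted marginal V
    phi = np.linalg.inv(vinv)
    imh = np.eye(n) - x @ bread @ u_mat.T  # I - H
    bphib = imh @ phi @ imh.T
    c_mat = np.zeros((q, p))
    for r, j in enumerate(coef_idx):
        c_mat[r, j] = 1.0

    meat = np.zeros((p, p))
    p_blocks = []
    for rows in row_sets:
        phi_ii = phi[np.ix_(rows, rows)]
        b_i = bphib[np.ix_(rows, rows)]
        # A_i such that A_i B_i A_i = Phi_ii  (CR2 bias correction)
        phi_half = _sym_power(phi_ii, 0.5)
        a_i = phi_half @ _sym_power(phi_half @ b_i @ phi_half, -0.5) @ phi_half
        ue = u_mat[rows].T @ (a_i @ resid[rows])
        meat += np.outer(ue, ue)
        p_blocks.append(a_i @ u_mat[rows] @ bread @ c_mat.T)  # n_i x q
    vc = bread @ meat @ bread
    vc = (vc + vc.T) / 2.0

    # approximate Hotelling df: match the first two moments of the q x q
    # meat (in the contrast space) to a Wishart under the working model
    omega = np.zeros((q, q))
    for rows, pb in zip(row_sets, p_blocks):
        omega += pb.T @ phi[np.ix_(rows, rows)] @ pb
    omega_isqrt = _sym_power(omega, -0.5)
    denom = 0.0
    for i, (rows_i, pi) in enumerate(zip(row_sets, p_blocks)):
        for rows_j, pj in zip(row_sets, p_blocks):
            t_ij = omega_isqrt @ (pi.T @ phi[np.ix_(rows_i, rows_j)] @ pj) @ omega_isqrt
            denom += np.trace(t_ij) ** 2 + np.trace(t_ij @ t_ij)
    nu = q * (q + 1) / denom if denom > 0 else float(m - p)
    df2 = max(nu - q + 1, 1.0)

    bsel = result.coefficients[coef_idx]
    vsel = vc[np.ix_(coef_idx, coef_idx)]
    wald = float(bsel @ np.linalg.solve(vsel, bsel))
    stat = (df2 / (nu * q)) * wald
    pval = float(f_dist.sf(stat, q, df2))
    result.robust = {"F": stat, "df1": q, "df2": df2, "p": pval, "vcov": vc,
                     "method": method, "nu": nu}
    return stat, float(q), float(df2), pval


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in sorted
    order, capped at 1). Adjust each test family separately."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
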