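"""Unconstrained multi-component GREML.

Fits, per phenotype, the linear mixed model

    y = X b + sum_i u_i + e,   V = sum_i s2_i A_i + s2_e I

by restricted maximum likelihood, where the A_i are genetic relationship
matrices. Optimization uses one expectation-maximization warm-start
iteration followed by average-information (AI) updates; variance
components are *not* constrained to be positive, so negative estimates
(and negative heritability ratios) are legal output. When the assembled V
is not positive definite — which can happen with negative components —
eigenvalue bending raises the deficient eigenvalues before inversion.

With the four-GRM model (genome-wide-minus-loci, thresholded pedigree,
class-hit loci, notclass-hit loci) the composite heritabilities are

    h2_g        = V(G1)/Vp          h2_ped      = V(G2)/Vp
    h2_class    = V(G3)/Vp          h2_notclass = V(G4)/Vp
    h2_metabolite_hits = (V(G3)+V(G4))/Vp
    h2_snp      = (V(G1)+V(G3)+V(G4))/Vp
    h2_total    = (V(G1)+V(G2)+V(G3)+V(G4))/Vp

with Vp the sum of all five components. Standard errors of these ratios
are obtained by Monte-Carlo resampling of the variance components from
the inverse-AI parameter covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "HeritabilityEstimate",
    "LRTResult",
    "VarianceModelFit",
    "composite_heritabilities",
    "fit_reml",
    "lrt_reduced",
    "mc_standard_errors",
    "reml_loglik",
]

_H2_NAMES = [
    "h2_g", "h2_ped", "h2_class_hits", "h2_notclass_hits",
    "h2_metabolite_hits", "h2_snp", "h2_total",
]


@dataclass
class VarianceModelFit:
    """REML estimates of the variance components and their uncertainty.

    ``estimates`` holds (V(G1), ..., V(Gk), V(e)); ``param_covariance`` is
    the inverse average-information matrix at the final iterate.
    """

    estimates: np.ndarray
    Vp: float
    fixed_effects: np.ndarray
    param_covariance: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    bent: bool
    component_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.estimates)


@dataclass
class HeritabilityEstimate:
    """Composite heritability ratios with (optionally) their s.e.'s."""

    h2_g: float
    h2_ped: float
    h2_class_hits: float
    h2_notclass_hits: float
    h2_metabolite_hits: float
    h2_snp: float
    h2_total: float
    se: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _H2_NAMES}


@dataclass
class LRTResult:
    dropped: tuple[str, ...]
    loglik_full: float
    loglik_reduced: float
    statistic: float
    pvalue: float | None
    reduced_converged: bool


def _as_matrices(grms) -> list[np.ndarray]:
    mats = []
    for g in grms:
        mats.append(np.asarray(g.matrix if hasattr(g, "matrix") else g, dtype=float))
    return mats


def _assemble_v(variances, mats, n) -> np.ndarray:
    v = variances[-1] * np.eye(n)
    for s2, a in zip(variances[:-1], mats):
        v += s2 * a
    return v


def _bend(v: np.ndarray, floor_frac: float = 1e-8) -> np.ndarray:
    """Raise eigenvalues of V below floor_frac * max-eigenvalue to that
    floor so the matrix can be inverted."""
    w, u = np.linalg.eigh(v)
    floor = floor_frac * w.max()
    if floor <= 0:
        floor = floor_frac
    w = np.maximum(w, floor)
    return (u * w) @ u.T


def _invert_v(v: np.ndarray, bend: bool):
    """(V^-1, logdet V, bent flag); Cholesky first, bending on failure."""
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        vinv = linalg.cho_solve((c, low), np.eye(v.shape[0]), check_finite=False)
        return vinv, logdet, False
    except np.linalg.LinAlgError:
        pass
    except linalg.LinAlgError:
        pass
    if not bend:
        raise np.linalg.LinAlgError("V is not positive definite (bending disabled)")
    vb = _bend(v)
    c, low = linalg.cho_factor(vb, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = linalg.cho_solve((c, low), np.eye(v.shape[0]), check_finite=False)
    return vinv, logdet, True


def _projection(vinv, x):
    """P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 and pieces."""
    vx = vinv @ x
    xtvx = x.T @ vx
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X not positive definite")
    xtvx_inv = np.linalg.inv(xtvx)
    p = vinv - vx @ xtvx_inv @ vx.T
    return p, logdet_xtvx, xtvx_inv, vx


def _restricted_ll(variances, y, x, mats, bend):
    n, p = x.shape
    v = _assemble_v(np.asarray(variances, dtype=float), mats, n)
    vinv, logdet_v, bent = _invert_v(v, bend)
    pm, logdet_xtvx, _, _ = _projection(vinv, x)
    py = pm @ y
    ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet_v + logdet_xtvx + float(y @ py))
    return ll, pm, py, bent


def reml_loglik(variances, y, X, grms, bend: bool = False) -> float:
    """Restricted log-likelihood of the variance components (including the
    residual component as the last entry). Deterministic; raises if the
    assembled V is singular and bending is disabled."""
    y = np.asarray(y, dtype=float)
    x = _design(X, y.size)
    mats = _as_matrices(grms)
    ll, _, _, _ = _restricted_ll(variances, y, x, mats, bend)
    return float(ll)


def _design(X, n) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    x = np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def fit_reml(
    y,
    X,
    grms,
    max_iter: int = 100,
    tol: float = 1e-8,
    bend: bool = True,
    component_names: list[str] | None = None,
) -> VarianceModelFit:
    """AI-REML fit of the multi-GRM variance-component model.

    One EM warm-start iteration, then average-information updates with
    step halving whenever a proposed step lowers the restricted
    log-likelihood. Convergence when the log-likelihood change or the
    relative parameter change falls below ``tol``; a fit that exhausts
    ``max_iter`` is returned flagged non-converged rather than raised.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = _design(X, n)
    if x.shape[0] != n:
        raise ValueError("X rows must match length of y")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")
    mats = _as_matrices(grms)
    for a in mats:
        if a.shape != (n, n):
            raise ValueError("GRM dimension must match length of y")
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance")

    k = len(mats) + 1
    # starting values: equal split of the OLS residual variance
    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_ols
    vp0 = float(resid @ resid) / max(n - x.shape[1], 1)
    theta = np.full(k, vp0 / k)

    ll, pm, py, bent_any = -np.inf, None, None, False
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        ll_new, pm, py, bent = _restricted_ll(theta, y, x, mats, bend)
        bent_any |= bent

        # score dL/ds2_i = -1/2 (tr(P A_i) - y'P A_i P y) and AI matrix
        # AI_ij = 1/2 y'P A_i P A_j P y
        apy = [a @ py for a in mats] + [py]
        tr_pa = [float(np.sum(pm * a)) for a in mats] + [float(np.trace(pm))]
        score = np.array(
            [-0.5 * (tr_pa[i] - float(py @ apy[i])) for i in range(k)]
        )
        m = np.column_stack(apy)
        ai = 0.5 * (m.T @ (pm @ m))

        if it > 1 and abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break

        if it == 1:
            # EM warm start: s2 <- s2 + 2 s2^2 * score / n
            theta_new = theta + 2.0 * theta**2 * score / n
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(ai, score, rcond=None)[0]
            theta_new = theta + delta
            # step halving if the likelihood would decrease
            step = 1.0
            for _ in range(15):
                try:
                    ll_try, *_ = _restricted_ll(theta + step * delta, y, x, mats, bend)
                except np.linalg.LinAlgError:
                    ll_try = -np.inf
                if ll_try >= ll_new - 1e-10:
                    theta_new = theta + step * delta
                    break
                step /= 2.0
            else:
                theta_new = theta + 2.0 * theta**2 * score / n  # EM fallback

        rel = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))
        theta, ll = theta_new, ll_new
        if it > 1 and rel < tol:
            converged = True
            break

    if not converged:
        logger.warning("fit_reml: no convergence after %d iterations", max_iter)

    # final likelihood / AI at the returned parameters
    ll_fin, pm, py, bent = _restricted_ll(theta, y, x, mats, bend)
    bent_any |= bent
    apy = [a @ py for a in mats] + [py]
    m = np.column_stack(apy)
    ai = 0.5 * (m.T @ (pm @ m))
    try:
        param_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        param_cov = np.linalg.pinv(ai)
        logger.warning("fit_reml: AI matrix singular; using pseudo-inverse")
    param_cov = (param_cov + param_cov.T) / 2.0

    vinv, _, _ = _invert_v(_assemble_v(theta, mats, n), bend)
    _, _, xtvx_inv, vx = _projection(vinv, x)
    beta = xtvx_inv @ (vx.T @ y)

    if component_names is None:
        component_names = [f"V(G{i + 1})" for i in range(len(mats))] + ["V(e)"]
    return VarianceModelFit(
        estimates=theta,
        Vp=float(theta.sum()),
        fixed_effects=beta,
        param_covariance=param_cov,
        loglik=float(ll_fin),
        converged=converged,
        n_iter=n_iter,
        bent=bent_any,
        component_names=component_names,
    )


def composite_heritabilities(fit: VarianceModelFit) -> HeritabilityEstimate:
    """Composite heritability ratios from a four-GRM fit (five components)."""
    if fit.n_components != 5:
        raise ValueError("composite heritabilities require a four-GRM (five-component) fit")
    v1, v2, v3, v4, _ = fit.estimates
    vp = fit.Vp
    if vp <= 0:
        raise ValueError("nonpositive phenotypic variance")
    return HeritabilityEstimate(
        h2_g=v1 / vp,
        h2_ped=v2 / vp,
        h2_class_hits=v3 / vp,
        h2_notclass_hits=v4 / vp,
        h2_metabolite_hits=(v3 + v4) / vp,
        h2_snp=(v1 + v3 + v4) / vp,
        h2_total=(v1 + v2 + v3 + v4) / vp,
    )


# composite ratios as linear combinations of (V1..V4, Ve) over Vp
_RATIO_NUMERATORS = {
    "h2_g": np.array([1, 0, 0, 0, 0.0]),
    "h2_ped": np.array([0, 1, 0, 0, 0.0]),
    "h2_class_hits": np.array([0, 0, 1, 0, 0.0]),
    "h2_notclass_hits": np.array([0, 0, 0, 1, 0.0]),
    "h2_metabolite_hits": np.array([0, 0, 1, 1, 0.0]),
    "h2_snp": np.array([1, 0, 1, 1, 0.0]),
    "h2_total": np.array([1, 1, 1, 1, 0.0]),
}


def mc_standard_errors(
    fit: VarianceModelFit,
    n_draws: int = 10_000,
    seed: int = 0,
    components: str = "g1_g3_g4",
) -> dict[str, float]:
    """Monte-Carlo standard errors of the composite heritability ratios.

    Draws ``n_draws`` variance vectors from a multivariate normal centered
    at the estimates with the (sub)matrix of the parameter covariance, then
    takes the standard deviation of each ratio across draws, recomputing Vp
    per draw. ``components`` selects which variances co-vary: the default
    samples (V(G1), V(G3), V(G4)) jointly with V(G2) and V(e) held at their
    estimates; ``"all"`` uses the full covariance. Draws with |Vp| below
    1e-12 of the estimated Vp are rejected and logged.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if fit.n_components != 5:
        raise ValueError("MC standard errors require a five-component fit")
    idx = [0, 2, 3] if components == "g1_g3_g4" else list(range(5))
    sigma = fit.param_covariance[np.ix_(idx, idx)]
    w, u = np.linalg.eigh((sigma + sigma.T) / 2.0)
    if (w < -1e-10 * max(w.max(), 1.0)).any():
        logger.warning("mc_standard_errors: projecting negative covariance eigenvalues to 0")
    root = u * np.sqrt(np.clip(w, 0, None))

    rng = np.random.default_rng(seed)
    draws = np.tile(fit.estimates, (n_draws, 1))
    draws[:, idx] = fit.estimates[idx] + rng.standard_normal((n_draws, len(idx))) @ root.T

    vp = draws.sum(axis=1)
    ok = np.abs(vp) >= 1e-12 * abs(fit.Vp)
    n_rej = int((~ok).sum())
    if n_rej:
        logger.warning("mc_standard_errors: rejected %d draw(s) with near-zero Vp", n_rej)
    draws, vp = draws[ok], vp[ok]

    ses = {}
    for name, c in _RATIO_NUMERATORS.items():
        ratio = draws @ c / vp
        ses[name] = float(np.std(ratio, ddof=1))
    return ses


_DROP_ALIASES = {
    "V(G3)": 2, "V(G4)": 3, "class": 2, "notclass": 3, "class_hits": 2,
    "notclass_hits": 3,
}


def lrt_reduced(y, X, grms, fit_full: VarianceModelFit, drop, **fit_kwargs) -> LRTResult:
    """Likelihood-ratio test of dropping the class-hit and/or notclass-hit
    components from the full four-GRM model.

    The statistic is max(0, 2 * (ll_full - ll_reduced)) referred to a
    chi-square with df equal to the number of dropped components (the
    components are unconstrained, so the null is interior, not on a
    boundary). A non-convergent reduced fit is flagged and returns a null
    p-value.
    """
    drop = tuple(drop) if not isinstance(drop, str) else (drop,)
    if not drop:
        raise ValueError("drop must name at least one of the locus components")
    idx = sorted({_DROP_ALIASES.get(d, d) for d in drop})
    if not set(idx) <= {2, 3}:
        raise ValueError("only the class-hits (V(G3)) and notclass-hits (V(G4)) "
                         "components may be dropped")
    mats = _as_matrices(grms)
    if len(mats) != 4:
        raise ValueError("lrt_reduced expects the four-GRM full model")
    reduced = [m for i, m in enumerate(mats) if i not in idx]
    fit_red = fit_reml(y, X, reduced, **fit_kwargs)
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
    pval = float(chi2.sf(stat, df=len(idx))) if fit_red.converged else None
    if not fit_red.converged:
        logger.warning("lrt_reduced: reduced model did not converge")
    names = tuple(f"V(G{i + 1})" for i in idx)
    return LRTResult(
        dropped=names,
        loglik_full=float(fit_full.loglik),
        loglik_reduced=float(fit_red.loglik),
        statistic=float(stat),
        pvalue=pval,
        reduced_converged=fit_red.converged,
    )
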