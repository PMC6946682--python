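"""AI-REML variance components: oracle equivalence, invariances, composite
heritability arithmetic, Monte-Carlo standard errors and LRTs."""

import numpy as np
import pytest
from scipy.optimize import minimize

from metaherit import (
    composite_heritabilities,
    fit_reml,
    lrt_reduced,
    mc_standard_errors,
    reml_loglik,
)
from metaherit.reml import VarianceModelFit
from metaherit.simulate import expected_relationship_matrix, simulate_pedigree


def random_grm(n, m, seed):
    z = np.random.default_rng(seed).standard_normal((n, m))
    return z @ z.T / m


def direct_reml_maximum(y, X, mats, starts):
    """Derivative-free oracle: Nelder-Mead maximization of the restricted
    likelihood surface from several starts."""
    f = lambda th: -reml_loglik(th, y, X, mats, bend=True)
    best = None
    for s in starts:
        r = minimize(f, s, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 8000})
        if best is None or r.fun < best.fun:
            best = r
    return best.x, -best.fun


class TestFitReml:
    def test_constant_phenotype_rejected(self):
        grm = random_grm(20, 50, 0)
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            fit_reml(np.ones(20), None, [grm])

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            fit_reml(y, X, [random_grm(20, 50, 0)])

    def test_matches_derivative_free_oracle_two_grms(self):
        rng = np.random.default_rng(5)
        n = 30
        a1 = random_grm(n, 60, 2)
        a2 = expected_relationship_matrix(simulate_pedigree(15, {"mz_pair": 1.0}, seed=3))
        y = rng.multivariate_normal(np.zeros(n), 0.4 * a1 + 0.3 * a2 + 0.3 * np.eye(n))
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = fit_reml(y, X, [a1, a2])
        est, ll = direct_reml_maximum(
            y, X, [a1, a2],
            starts=[fit.estimates * 0 + np.var(y) / 3, (0.5, 0.2, 0.3), (0.1, 0.1, 0.8)],
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-4)
        assert fit.estimates == pytest.approx(est, abs=1e-3)

    def test_matches_anova_closed_form_on_balanced_mz_design(self):
        m = 80
        ped = simulate_pedigree(m, {"mz_pair": 1.0}, seed=7)
        K = expected_relationship_matrix(ped)
        n = 2 * m
        rng = np.random.default_rng(8)
        y = rng.multivariate_normal(np.zeros(n), 0.45 * K + 0.55 * np.eye(n))
        fit = fit_reml(y, None, [K])
        pairs = y.reshape(m, 2)
        pm, gm = pairs.mean(axis=1), y.mean()
        msb = 2 * np.sum((pm - gm) ** 2) / (m - 1)
        msw = np.sum((pairs - pm[:, None]) ** 2) / m
        icc = (msb - msw) / (msb + msw)
        assert fit.estimates[0] / fit.estimates.sum() == pytest.approx(icc, abs=1e-6)

    def test_fitted_point_is_local_maximum(self):
        rng = np.random.default_rng(9)
        n = 40
        a = random_grm(n, 80, 4)
        y = rng.multivariate_normal(np.zeros(n), 0.5 * a + 0.5 * np.eye(n))
        fit = fit_reml(y, None, [a])
        ll_hat = reml_loglik(fit.estimates, y, None, [a], bend=True)
        for _ in range(100):
            pert = fit.estimates + rng.normal(0, 0.02, size=2)
            try:
                assert reml_loglik(pert, y, None, [a], bend=True) <= ll_hat + 1e-8
            except np.linalg.LinAlgError:
                continue

    def test_duplicate_grm_reparameterization_invariance(self):
        rng = np.random.default_rng(10)
        n = 25
        a = random_grm(n, 50, 5)
        y = rng.multivariate_normal(np.zeros(n), 0.6 * a + 0.4 * np.eye(n))
        fit = fit_reml(y, None, [a])
        s = fit.estimates[0]
        ll_split = reml_loglik([0.3 * s, 0.7 * s, fit.estimates[1]], y, None, [a, a], bend=True)
        assert ll_split == pytest.approx(fit.loglik, abs=1e-8)

    def test_scaling_phenotype_scales_variances_not_ratios(self):
        rng = np.random.default_rng(11)
        n = 30
        a = random_grm(n, 60, 6)
        y = rng.multivariate_normal(np.zeros(n), 0.5 * a + 0.5 * np.eye(n))
        f1 = fit_reml(y, None, [a])
        f2 = fit_reml(3.0 * y, None, [a])
        assert f2.estimates == pytest.approx(9.0 * f1.estimates, rel=1e-4)
        assert f2.estimates[0] / f2.estimates.sum() == pytest.approx(
            f1.estimates[0] / f1.estimates.sum(), abs=1e-6
        )

    def test_bending_allows_negative_component_fits(self):
        # a phenotype with less family resemblance than expected drives the
        # genetic component negative; the fit must remain legal output
        rng = np.random.default_rng(12)
        n = 60
        a = expected_relationship_matrix(simulate_pedigree(30, {"mz_pair": 1.0}, seed=13))
        y = rng.standard_normal(n)  # no family resemblance at all
        fit = fit_reml(y, None, [a])
        assert np.isfinite(fit.loglik)


def make_fit(estimates, cov):
    estimates = np.asarray(estimates, dtype=float)
    return VarianceModelFit(
        estimates=estimates, Vp=float(estimates.sum()),
        fixed_effects=np.zeros(1), param_covariance=np.asarray(cov, dtype=float),
        loglik=0.0, converged=True, n_iter=1, bent=False,
        component_names=["V(G1)", "V(G2)", "V(G3)", "V(G4)", "V(e)"],
    )


class TestComposites:
    def test_pure_noise_gives_zero_heritability(self):
        h2 = composite_heritabilities(make_fit([0, 0, 0, 0, 1], np.zeros((5, 5))))
        assert all(v == 0 for v in h2.as_dict().values())

    def test_forced_arithmetic(self):
        h2 = composite_heritabilities(
            make_fit([0.2, 0.1, 0.05, 0.01, 0.64], np.zeros((5, 5)))
        )
        assert h2.h2_total == pytest.approx(0.36)
        assert h2.h2_snp == pytest.approx(0.26)
        assert h2.h2_metabolite_hits == pytest.approx(0.06)
        assert h2.h2_metabolite_hits == pytest.approx(h2.h2_class_hits + h2.h2_notclass_hits)

    def test_negative_class_component_is_legal(self):
        h2 = composite_heritabilities(
            make_fit([0.5, 0.0, -0.02, 0.0, 0.52], np.zeros((5, 5)))
        )
        assert h2.h2_class_hits == pytest.approx(-0.02)

    def test_nonpositive_vp_rejected(self):
        with pytest.raises(ValueError):
            composite_heritabilities(make_fit([0.1, 0, 0, 0, -0.1], np.zeros((5, 5))))


class TestMcStandardErrors:
    def test_zero_covariance_gives_zero_se(self):
        ses = mc_standard_errors(
            make_fit([0.3, 0.1, 0.05, 0.02, 0.53], np.zeros((5, 5))), n_draws=100, seed=0
        )
        assert all(abs(v) < 1e-12 for v in ses.values())

    def test_fixed_seed_deterministic(self):
        cov = np.diag([0.01, 0.0, 0.005, 0.002, 0.0])
        fit = make_fit([0.3, 0.1, 0.05, 0.02, 0.53], cov)
        a = mc_standard_errors(fit, n_draws=2000, seed=5)
        b = mc_standard_errors(fit, n_draws=2000, seed=5)
        assert a == b

    def test_within_15_percent_of_delta_method(self):
        rng = np.random.default_rng(7)
        n = 300
        mats = [random_grm(n, 250, 10 + i) for i in range(4)]
        v = 0.25 * mats[0] + 0.2 * mats[1] + 0.1 * mats[2] + 0.05 * mats[3] + 0.4 * np.eye(n)
        y = rng.multivariate_normal(np.zeros(n), v)
        fit = fit_reml(y, None, mats)
        ses = mc_standard_errors(fit, n_draws=10_000, seed=2, components="all")
        est, cov = fit.estimates, fit.param_covariance
        vp, ones = est.sum(), np.ones(5)
        from metaherit.reml import _RATIO_NUMERATORS

        for name, c in _RATIO_NUMERATORS.items():
            grad = c / vp - (c @ est) * ones / vp**2
            delta = float(np.sqrt(grad @ cov @ grad))
            assert ses[name] == pytest.approx(delta, rel=0.15)

    def test_paper_mode_holds_pedigree_component_fixed(self):
        cov = np.diag([0.01, 0.02, 0.005, 0.002, 0.03])
        fit = make_fit([0.3, 0.1, 0.05, 0.02, 0.53], cov)
        ses = mc_standard_errors(fit, n_draws=5000, seed=1, components="g1_g3_g4")
        # V(G2) is held at its estimate, so h2_ped varies only through Vp
        assert ses["h2_ped"] < ses["h2_g"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            mc_standard_errors(make_fit([0.3, 0.1, 0.05, 0.02, 0.53], np.zeros((5, 5))),
                               n_draws=1)


@pytest.fixture(scope="module")
def fitted(four_grms, cohort):
    y = cohort["panel"].values["met001"].to_numpy()
    fit = fit_reml(y, None, four_grms)
    return y, fit


class TestLrt:
    def test_statistic_nonnegative_and_df_matches_drop(self, fitted, four_grms):
        y, fit = fitted
        for drop in [["V(G3)"], ["V(G4)"], ["V(G3)", "V(G4)"]]:
            res = lrt_reduced(y, None, four_grms, fit, drop=drop)
            assert res.statistic >= 0.0
            assert len(res.dropped) == len(drop)
            assert res.pvalue is None or 0 <= res.pvalue <= 1

    def test_dropping_active_class_component_is_detected(self, cohort, four_grms):
        # strong class-hit signal (fraction 0.15) on the same loci: the LRT
        # against the reduced model must reject
        import dataclasses

        from metaherit import simulate_metabolites

        arch = dataclasses.replace(
            cohort["arch"], var_fractions=(0.20, 0.10, 0.15, 0.02, 0.53)
        )
        panel = simulate_metabolites(cohort["geno"], arch, cohort["ped"], seed=77)
        y = panel.values["met001"].to_numpy()
        fit = fit_reml(y, None, four_grms)
        res = lrt_reduced(y, None, four_grms, fit, drop=["V(G3)"])
        assert res.pvalue < 0.01

    def test_invalid_drop_rejected(self, fitted, four_grms):
        y, fit = fitted
        with pytest.raises(ValueError):
            lrt_reduced(y, None, four_grms, fit, drop=["V(G1)"])
        with pytest.raises(ValueError):
            lrt_reduced(y, None, four_grms, fit, drop=[])
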