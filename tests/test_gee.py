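"""Exchangeable GEE: exact reductions, closed-form oracles, robust
variance, cross-check against an independent implementation."""

import numpy as np
import pandas as pd
import pytest

from vitrehaze import CohortConfig, CollinearDesignError, fit_gee, generate_cohort, group_contrast
from vitrehaze.errors import VitrehazeError


def make_clustered(rng, n_clusters=50, cluster_size=2, subject_level_only=True,
                   rho=0.5, sd=0.4, betas=(0.5, -0.25)):
    rows = []
    for i in range(n_clusters):
        x1, x2 = rng.normal(size=2)
        u = rng.normal(0, np.sqrt(rho) * sd)
        for j in range(cluster_size):
            if not subject_level_only:
                x2 = rng.normal()
            e = rng.normal(0, np.sqrt(1 - rho) * sd)
            y = 1.0 + betas[0] * x1 + betas[1] * x2 + u + e
            rows.append({"subject_id": f"c{i:03d}", "x1": x1, "x2": x2, "y": y})
    return pd.DataFrame(rows)


class TestReductions:
    def test_singleton_clusters_equal_ols_exactly(self, rng):
        d = make_clustered(rng, n_clusters=60, cluster_size=1)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        X = np.column_stack([np.ones(len(d)), d.x1, d.x2])
        beta_ols, *_ = np.linalg.lstsq(X, d.y.to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols, rtol=1e-12)

    def test_balanced_clusters_match_closed_form_gls(self, rng):
        d = make_clustered(rng, n_clusters=50, cluster_size=2)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        # closed-form GLS with compound-symmetry covariance at the fitted rho
        rho = fit.rho_hat
        X = np.column_stack([np.ones(len(d)), d.x1, d.x2])
        y = d.y.to_numpy()
        Vinv_block = np.linalg.inv(np.array([[1, rho], [rho, 1]]))
        Vinv = np.kron(np.eye(50), Vinv_block)
        beta_gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_gls, rtol=1e-6)

    def test_sandwich_matches_textbook_loop(self, rng):
        d = make_clustered(rng, n_clusters=40, cluster_size=2,
                           subject_level_only=False)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        rho, phi = fit.rho_hat, fit.phi_hat
        X = np.column_stack([np.ones(len(d)), d.x1, d.x2])
        y = d.y.to_numpy()
        beta = fit.params.to_numpy()
        R = np.array([[1, rho], [rho, 1]])
        A = np.zeros((3, 3))
        M = np.zeros((3, 3))
        for i in range(40):
            sl = slice(2 * i, 2 * i + 2)
            Xi, ri = X[sl], y[sl] - X[sl] @ beta
            Vinv = np.linalg.inv(phi * R)
            A += Xi.T @ Vinv @ Xi
            g = Xi.T @ Vinv @ ri
            M += np.outer(g, g)
        cov = np.linalg.inv(A) @ M @ np.linalg.inv(A)
        np.testing.assert_allclose(fit.cov_robust, cov, rtol=1e-8)


class TestCrossCheck:
    def test_against_statsmodels_gee(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        d = make_clustered(rng, n_clusters=120, cluster_size=2,
                           subject_level_only=False)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        X = np.column_stack([np.ones(len(d)), d.x1, d.x2])
        model = sm.GEE(d.y, X, groups=d.subject_id,
                       cov_struct=sm.cov_struct.Exchangeable(),
                       family=sm.families.Gaussian())
        res = model.fit()
        np.testing.assert_allclose(fit.params.to_numpy(), res.params, atol=1e-4)
        np.testing.assert_allclose(fit.robust_se.to_numpy(), res.bse, rtol=0.05)


class TestDiagnostics:
    def test_collinear_design_named(self, rng):
        d = make_clustered(rng, n_clusters=30)
        d["x3"] = 2 * d.x1
        with pytest.raises(CollinearDesignError) as exc:
            fit_gee(d, "y", ["x1", "x2", "x3"], "subject_id")
        assert any(c in exc.value.columns for c in ("x1", "x3"))

    def test_too_few_clusters_rejected(self, rng):
        d = make_clustered(rng, n_clusters=1, cluster_size=2)
        with pytest.raises(VitrehazeError):
            fit_gee(d, "y", ["x1"], "subject_id")

    def test_missing_rows_dropped(self, rng):
        d = make_clustered(rng, n_clusters=30)
        d.loc[d.index[:6], "x1"] = np.nan
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        assert fit.n_obs == len(d) - 6

    def test_rho_recovery_null_model(self):
        cfg = CohortConfig(
            n_patients=500, n_controls=0,
            beta_age=0, beta_duration=0, beta_sex_male=0, beta_prnfl=0,
            beta_gcipl=0, beta_ngmv=0, beta_nwmv=0, group_pct_difference=0,
            stratum_pct_vs_mild=(0, 0, 0), inter_eye_correlation=0.6,
        )
        subj, eyes = generate_cohort(cfg, seed=42)
        d = eyes.merge(subj, on="subject_id")
        d["male"] = (d.sex == "M").astype(float)
        fit = fit_gee(d, "log_vh", ["age", "male"], "subject_id")
        assert abs(fit.rho_hat - 0.6) < 0.05

    def test_type_one_error_of_robust_wald(self):
        cfg = CohortConfig(
            n_patients=300, n_controls=0,
            beta_age=0, beta_duration=0, beta_sex_male=0, beta_prnfl=0,
            beta_gcipl=0, beta_ngmv=0, beta_nwmv=0, group_pct_difference=0,
            stratum_pct_vs_mild=(0, 0, 0),
        )
        rejections = []
        for rep in range(300):
            subj, eyes = generate_cohort(cfg, seed=1000 + rep)
            d = eyes.merge(subj, on="subject_id")
            d["male"] = (d.sex == "M").astype(float)
            fit = fit_gee(d, "log_vh", ["gcipl_um", "age", "male"], "subject_id")
            rejections.append(fit.p_values["gcipl_um"] < 0.05)
        rate = np.mean(rejections)
        assert 0.03 <= rate <= 0.07


class TestGroupContrast:
    def test_zero_coefficient_is_zero_percent(self, rng):
        d = make_clustered(rng)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        fit.params["x1"] = 0.0
        assert group_contrast(fit, "x1") == 0.0

    @pytest.mark.parametrize("beta,pct", [
        (np.log(1.0958), 9.58),
        (-0.3, (np.exp(-0.3) - 1) * 100),
    ])
    def test_percent_difference_inverse(self, rng, beta, pct):
        d = make_clustered(rng)
        fit = fit_gee(d, "y", ["x1", "x2"], "subject_id")
        fit.params["x1"] = beta
        assert group_contrast(fit, "x1") == pytest.approx(pct, rel=1e-9)

    def test_missing_term_rejected(self, rng):
        d = make_clustered(rng)
        fit = fit_gee(d, "y", ["x1"], "subject_id")
        with pytest.raises(VitrehazeError):
            group_contrast(fit, "nope")
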