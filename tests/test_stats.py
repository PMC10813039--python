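"""QC accounting, EDSS stratification, subject-level tests and the
association suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vitrehaze import (
    CohortConfig,
    apply_qc,
    chi_square_test,
    cohort_summary,
    fit_gee,
    generate_cohort,
    mann_whitney_u,
    run_association_suite,
    stratify_edss,
    stratum_counts,
)
from vitrehaze.errors import VitrehazeError


def qc_table(n_both_fail, n_ok, n_one_fail=0):
    rows = []
    sid = 0
    for _ in range(n_both_fail):
        rows += [{"subject_id": f"s{sid}", "qc_pass": False}] * 2
        sid += 1
    for _ in range(n_one_fail):
        rows += [{"subject_id": f"s{sid}", "qc_pass": True},
                 {"subject_id": f"s{sid}", "qc_pass": False}]
        sid += 1
    for _ in range(n_ok):
        rows += [{"subject_id": f"s{sid}", "qc_pass": True}] * 2
        sid += 1
    return pd.DataFrame(rows), sid


class TestApplyQc:
    def test_study_patient_accounting(self):
        # 316 eligible: 18 both-eye QC failures + 8 pathology -> 290 in, 8.2%
        eyes, sid = qc_table(n_both_fail=18, n_ok=316 - 18)
        pathology = [f"s{18 + i}" for i in range(8)]
        included, rep = apply_qc(eyes, pathology)
        assert rep.n_eligible == 316
        assert rep.n_included == 290 and len(included) == 290
        assert rep.rejection_rate_pct == 8.2

    def test_control_accounting(self):
        # 87 eligible controls, 1 pathology + 1 both-eye failure -> 85
        eyes, _ = qc_table(n_both_fail=1, n_ok=86)
        included, rep = apply_qc(eyes, ["s1"])
        assert rep.n_eligible == 87
        assert rep.n_included == 85

    def test_no_failures(self):
        eyes, _ = qc_table(0, 25)
        _inc, rep = apply_qc(eyes)
        assert rep.n_included == 25 and rep.rejection_rate_pct == 0.0

    def test_single_good_eye_keeps_subject(self):
        eyes, _ = qc_table(n_both_fail=0, n_ok=3, n_one_fail=4)
        _inc, rep = apply_qc(eyes)
        assert rep.n_included == 7


class TestStratifyEdss:
    @pytest.mark.parametrize("edss,label", [
        (0.0, "mild"), (3.5, "mild"), (4.0, "moderate"), (5.5, "moderate"),
        (6.0, "severe"), (8.0, "severe"), (10.0, "severe"),
    ])
    def test_threshold_boundaries(self, edss, label):
        assert stratify_edss([edss]).iloc[0] == label

    def test_study_stratum_percentages(self):
        # the published stratum counts over the published denominator
        labels = (["mild"] * 164) + (["moderate"] * 64) + (["severe"] * 63)
        out = stratum_counts(pd.Series(labels), total=290)
        assert out.set_index("stratum").loc["mild", "pct"] == 56.6
        assert out.set_index("stratum").loc["moderate", "pct"] == 22.1
        assert out.set_index("stratum").loc["severe", "pct"] == 21.7

    def test_off_lattice_rejected(self):
        with pytest.raises(VitrehazeError):
            stratify_edss([3.2])
        with pytest.raises(VitrehazeError):
            stratify_edss([11.0])

    def test_empty_input(self):
        assert len(stratify_edss([])) == 0


class TestMannWhitney:
    def test_complete_separation(self):
        u, _p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_symmetric(self):
        u, p = mann_whitney_u([5, 5, 5], [5, 5])
        assert u == 3 * 2 / 2
        assert p == 1.0

    def test_matches_pairwise_count_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 12, 20).astype(float)
            b = rng.integers(0, 12, 20).astype(float)
            u, _ = mann_whitney_u(a, b)
            brute = sum(1.0 if x > y else 0.5 if x == y else 0.0
                        for x in a for y in b)
            assert u == brute

    def test_p_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1, size=30)
        _u, p = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(VitrehazeError):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chi_square_test([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, _p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20 / 3, rel=1e-12)

    def test_study_sex_table_not_significant(self):
        # published female:male counts for patients vs controls
        stat, p = chi_square_test([[195, 95], [53, 32]])
        assert stat > 0
        assert p > 0.05

    def test_zero_expected_rejected(self):
        with pytest.raises(VitrehazeError):
            chi_square_test([[0, 0], [1, 2]])


@pytest.fixture(scope="module")
def cohort():
    cfg = CohortConfig(n_patients=250, n_controls=80)
    return generate_cohort(cfg, seed=5)


class TestAssociationSuite:
    def test_single_model_equals_direct_fit(self, cohort):
        subj, eyes = cohort
        res = run_association_suite(eyes, subj)
        row = res[(res.cohort == "MS") & (res.stratum == "all")
                  & (res.covariate == "gcipl_um")].iloc[0]
        d = eyes.merge(subj, on="subject_id")
        d["male"] = (d.sex == "M").astype(float)
        fit = fit_gee(d[d.group == "MS"], "log_vh", ["gcipl_um", "age", "male"],
                      "subject_id")
        assert row.beta == pytest.approx(fit.params["gcipl_um"], rel=1e-12)
        assert row.p == pytest.approx(fit.p_values["gcipl_um"], rel=1e-12)
        assert row.n_obs == fit.n_obs

    def test_layout_covers_cohorts_strata_and_contrasts(self, cohort):
        subj, eyes = cohort
        res = run_association_suite(eyes, subj)
        assert set(res.cohort) >= {"MS", "HC", "MS+HC"}
        assert {"mild", "moderate", "severe", "all"} <= set(res.stratum)
        assert "MS_vs_HC" in set(res.covariate)
        assert "severe_vs_mild" in set(res.covariate)
        # HC rows never carry MS-only covariates
        hc = res[res.cohort == "HC"]
        assert not set(hc.covariate) & {"disease_duration", "lesion_ml"}

    def test_tiny_stratum_flagged_not_estimable(self):
        cfg = CohortConfig(n_patients=12, n_controls=6,
                           edss_weights=(0.95, 0.04, 0.01))
        subj, eyes = generate_cohort(cfg, seed=9)
        res = run_association_suite(eyes, subj)
        sev = res[(res.stratum == "severe") & (res.covariate == "age")]
        if len(sev):
            assert not sev.iloc[0].estimable or sev.iloc[0].n_clusters >= 3

    def test_group_contrast_has_percent_difference(self, cohort):
        subj, eyes = cohort
        res = run_association_suite(eyes, subj)
        row = res[res.covariate == "MS_vs_HC"].iloc[0]
        assert row.estimable
        assert row.pct_diff == pytest.approx((np.exp(row.beta) - 1) * 100, rel=1e-9)


class TestCohortSummary:
    def test_group_means_and_tests_present(self):
        cfg = CohortConfig(n_patients=150, n_controls=60)
        subj, eyes = generate_cohort(cfg, seed=2)
        out = cohort_summary(eyes, subj)
        out = out.set_index("characteristic")
        assert out.loc["prnfl_um", "ms_mean"] < out.loc["prnfl_um", "hc_mean"]
        assert out.loc["age", "p"] == out.loc["age", "p"]  # finite
        assert np.isnan(out.loc["disease_duration", "hc_mean"])
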