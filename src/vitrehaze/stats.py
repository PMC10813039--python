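"""Cohort-level statistics: QC accounting, disability stratification,
subject-level group comparisons and the eye-level association suite.

All eye-level associations with log-VH are estimated with the
exchangeable GEE of :mod:`vitrehaze.gee`, adjusted for age and sex
(the age model is adjusted for sex only, and vice versa).  Subject-level
group comparisons use linear regression, the Mann-Whitney U test or the
chi-square test depending on variable type.  Disability is stratified
on the EDSS: mild 0.0-3.5, moderate 4.0-5.5, severe >= 6.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CollinearDesignError, VitrehazeError
from .gee import fit_gee

EDSS_STRATA = {
    "mild": (0.0, 3.5),
    "moderate": (4.0, 5.5),
    "severe": (6.0, 10.0),
}


# ---------------------------------------------------------------------------
# quality control accounting


@dataclass(frozen=True)
class QcReport:
    """Subject-level inclusion accounting after OCT quality control."""

    n_eligible: int
    n_excluded_qc: int
    n_excluded_pathology: int
    n_included: int
    rejection_rate_pct: float  # rounded to 1 decimal

    @property
    def n_excluded(self) -> int:
        return self.n_excluded_qc + self.n_excluded_pathology


def apply_qc(eye_qc: pd.DataFrame, pathology_subjects=()) -> tuple[set, QcReport]:
    """Apply consensus OCT quality control at the subject level.

    A subject is excluded if *both* eyes fail QC (a subject with one
    usable eye stays in), or if an ocular-pathology flag is set.

    Parameters
    ----------
    eye_qc : frame with columns ``subject_id`` and boolean ``qc_pass``,
        one row per eye.
    pathology_subjects : ids excluded for ocular pathology regardless of
        scan quality.
    """
    for c in ("subject_id", "qc_pass"):
        if c not in eye_qc.columns:
            raise VitrehazeError(f"eye_qc needs a {c!r} column")
    pathology = set(pathology_subjects)
    any_pass = eye_qc.groupby("subject_id")["qc_pass"].any()
    eligible = set(any_pass.index) | pathology
    qc_fail = {s for s, ok in any_pass.items() if not ok and s not in pathology}
    included = eligible - qc_fail - pathology
    n_eligible = len(eligible)
    n_excl = len(qc_fail) + len(pathology)
    rate = round(100.0 * n_excl / n_eligible, 1) if n_eligible else 0.0
    report = QcReport(
        n_eligible=n_eligible,
        n_excluded_qc=len(qc_fail),
        n_excluded_pathology=len(pathology),
        n_included=len(included),
        rejection_rate_pct=rate,
    )
    return included, report


# ---------------------------------------------------------------------------
# EDSS stratification


def stratify_edss(edss) -> pd.Series:
    """Label each EDSS score mild / moderate / severe.

    EDSS lives on the half-point lattice 0.0-10.0; off-lattice or
    out-of-range values raise.
    """
    e = pd.Series(edss, dtype=float)
    if e.isna().any():
        raise VitrehazeError("EDSS missing for some subjects")
    vals = e.to_numpy()
    if np.any((vals < 0) | (vals > 10)) or np.any(np.abs(vals * 2 - np.round(vals * 2)) > 1e-9):
        raise VitrehazeError("EDSS must lie on the 0.0-10.0 half-point lattice")
    out = pd.Series(index=e.index, dtype=object)
    for label, (lo, hi) in EDSS_STRATA.items():
        out[(vals >= lo) & (vals <= hi)] = label
    return out


def stratum_counts(strata: pd.Series, total: int | None = None) -> pd.DataFrame:
    """Counts and percentages (1 decimal) per disability stratum.

    ``total`` defaults to the number of labelled subjects; pass it
    explicitly to report percentages of a different inclusion base.
    """
    if total is None:
        total = len(strata)
    rows = []
    for label in EDSS_STRATA:
        n = int((strata == label).sum())
        pct = round(100.0 * n / total, 1) if total else 0.0
        rows.append({"stratum": label, "n": n, "pct": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subject-level tests


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U with tie-corrected normal approximation.

    Returns ``(U, p)`` where U counts pairs in which ``a`` exceeds
    ``b`` (ties count one half).  The two-sided p-value uses the normal
    approximation with tie correction and a 0.5 continuity correction;
    when every value is identical across both samples the test is
    degenerate and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise VitrehazeError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2 * sps.norm.sf(z)
    return float(u), float(min(p, 1.0))


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2 x k table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise VitrehazeError("contingency table must be 2-D")
    expected = sps.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise VitrehazeError("all expected counts must be positive")
    stat, p, _dof, _exp = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def linear_regression_test(y, x) -> tuple[float, float]:
    """Slope and two-sided p of a simple linear regression (subject level)."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# association suite


#: covariates regressed against log-VH, with the adjustment set used for
#: each (the covariate of interest is never its own adjuster)
ASSOCIATION_MODELS = (
    ("age", ("male",)),
    ("disease_duration", ("age", "male")),
    ("male", ("age",)),
    ("prnfl_um", ("age", "male")),
    ("gcipl_um", ("age", "male")),
    ("inl_um", ("age", "male")),
    ("ngmv_ml", ("age", "male")),
    ("nwmv_ml", ("age", "male")),
    ("nbv_ml", ("age", "male")),
    ("lesion_ml", ("age", "male")),
)

#: covariates that do not exist for healthy controls
MS_ONLY_COVARIATES = ("disease_duration", "lesion_ml")

MIN_CLUSTERS = 3


def _model_row(d, covariate, adjust, cohort, stratum):
    base = {
        "cohort": cohort,
        "stratum": stratum,
        "covariate": covariate,
        "n_obs": 0,
        "n_clusters": 0,
        "beta": np.nan,
        "se": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "p": np.nan,
        "rho_hat": np.nan,
        "converged": False,
        "estimable": False,
    }
    cols = ["log_vh", covariate, *adjust, "subject_id"]
    dd = d[[c for c in cols if c in d.columns]].dropna()
    if covariate not in d.columns or dd["subject_id"].nunique() < MIN_CLUSTERS:
        return base
    if dd[covariate].nunique() < 2:
        return base
    # adjusters that are constant in this subset carry no information and
    # would only make the design singular
    adjust = [a for a in adjust if dd[a].nunique() > 1]
    try:
        fit = fit_gee(dd, "log_vh", [covariate, *adjust], cluster="subject_id")
    except CollinearDesignError:
        # degenerate subset (e.g. a contrast indicator coinciding with an
        # adjuster in a tiny stratum): report the row as not estimable
        return base
    base.update(
        n_obs=fit.n_obs,
        n_clusters=fit.n_clusters,
        beta=fit.params[covariate],
        se=fit.robust_se[covariate],
        ci_low=fit.ci_low[covariate],
        ci_high=fit.ci_high[covariate],
        p=fit.p_values[covariate],
        rho_hat=fit.rho_hat,
        converged=fit.converged,
        estimable=True,
    )
    return base


def run_association_suite(eye_table: pd.DataFrame, subject_table: pd.DataFrame) -> pd.DataFrame:
    """Eye-level GEE associations of log-VH, mirroring the study layout.

    Runs every covariate model separately for the MS and HC cohorts,
    then re-runs the MS models inside each disability stratum, and adds
    group/phenotype/stratum contrasts with their percent differences on
    the haze scale.  Strata with fewer than 3 subjects are flagged
    not-estimable rather than fitted.
    """
    d = eye_table.merge(subject_table, on="subject_id", how="inner")
    if "male" not in d.columns and "sex" in d.columns:
        d["male"] = (d["sex"] == "M").astype(float)
    d = d[d.get("qc_pass", True) == True]  # noqa: E712

    rows = []
    for cohort, sub in (("MS", d[d.group == "MS"]), ("HC", d[d.group == "HC"])):
        for covariate, adjust in ASSOCIATION_MODELS:
            if cohort == "HC" and covariate in MS_ONLY_COVARIATES:
                continue
            rows.append(_model_row(sub, covariate, adjust, cohort, "all"))

    ms = d[d.group == "MS"].copy()
    if len(ms):
        ms["stratum"] = stratify_edss(ms["edss"]).to_numpy()
        for label in EDSS_STRATA:
            sub = ms[ms.stratum == label]
            for covariate, adjust in ASSOCIATION_MODELS:
                rows.append(_model_row(sub, covariate, adjust, "MS", label))

    out = pd.DataFrame(rows)
    contrasts = _contrast_rows(d, ms)
    return pd.concat([out, contrasts], ignore_index=True)


def _pairwise_contrast(d, mask_a, mask_b, label, cohort):
    """GEE contrast of group A vs reference B, age+sex adjusted."""
    sub = pd.concat([d[mask_a].assign(_ind=1.0), d[mask_b].assign(_ind=0.0)])
    row = _model_row(sub, "_ind", ("age", "male"), cohort, "all")
    row["covariate"] = label
    if row["estimable"]:
        row["pct_diff"] = float((np.exp(row["beta"]) - 1.0) * 100.0)
    else:
        row["pct_diff"] = np.nan
    return row


def _contrast_rows(d, ms) -> pd.DataFrame:
    rows = []
    is_ms = d.group == "MS"
    is_hc = d.group == "HC"
    if is_hc.any() and is_ms.any():
        rows.append(_pairwise_contrast(d, is_ms, is_hc, "MS_vs_HC", "MS+HC"))
        for pheno in ("RRMS", "SPMS", "PPMS"):
            rows.append(
                _pairwise_contrast(d, d.phenotype == pheno, is_hc, f"{pheno}_vs_HC", "MS+HC")
            )
        rows.append(
            _pairwise_contrast(
                d, d.phenotype.isin(["SPMS", "PPMS"]), d.phenotype == "RRMS",
                "PMS_vs_RRMS", "MS",
            )
        )
    if len(ms):
        s = ms.stratum
        rows.append(_pairwise_contrast(ms, s == "severe", s == "mild", "severe_vs_mild", "MS"))
        rows.append(
            _pairwise_contrast(ms, s == "severe", s == "moderate", "severe_vs_moderate", "MS")
        )
        rows.append(
            _pairwise_contrast(ms, s == "moderate", s == "mild", "moderate_vs_mild", "MS")
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort summary (study-characteristics table)


def cohort_summary(eye_table: pd.DataFrame, subject_table: pd.DataFrame) -> pd.DataFrame:
    """Group means (SD) and MS-vs-HC test per characteristic."""
    d = eye_table.merge(subject_table, on="subject_id", how="inner")
    subj = subject_table
    ms_s = subj[subj.group == "MS"]
    hc_s = subj[subj.group == "HC"]
    rows = []

    def add(name, ms_vals, hc_vals, test):
        ms_vals = pd.Series(ms_vals).dropna()
        hc_vals = pd.Series(hc_vals).dropna()
        p = np.nan
        if len(hc_vals) and test == "mwu":
            _u, p = mann_whitney_u(ms_vals, hc_vals)
        elif len(hc_vals) and test == "lin":
            g = np.r_[np.ones(len(ms_vals)), np.zeros(len(hc_vals))]
            _b, p = linear_regression_test(np.r_[ms_vals, hc_vals], g)
        rows.append(
            {
                "characteristic": name,
                "ms_mean": ms_vals.mean() if len(ms_vals) else np.nan,
                "ms_sd": ms_vals.std(ddof=1) if len(ms_vals) > 1 else np.nan,
                "hc_mean": hc_vals.mean() if len(hc_vals) else np.nan,
                "hc_sd": hc_vals.std(ddof=1) if len(hc_vals) > 1 else np.nan,
                "p": p,
            }
        )

    add("age", ms_s.age, hc_s.age, "lin")
    add("disease_duration", ms_s.disease_duration, [], None)
    for col in ("prnfl_um", "gcipl_um", "inl_um"):
        e = d[d.get("qc_pass", True) == True]  # noqa: E712
        add(col, e.loc[e.group == "MS", col], e.loc[e.group == "HC", col], "lin")
    for col in ("ngmv_ml", "nwmv_ml"):
        add(col, ms_s[col], hc_s[col], "lin")
    e = d[d.get("qc_pass", True) == True]  # noqa: E712
    add("vh_ratio", e.loc[e.group == "MS", "vh_ratio"], e.loc[e.group == "HC", "vh_ratio"], "mwu")

    # sex distribution chi-square
    tab = np.array(
        [
            [(ms_s.sex == "F").sum(), (ms_s.sex == "M").sum()],
            [(hc_s.sex == "F").sum(), (hc_s.sex == "M").sum()],
        ]
    )
    p_sex = chi_square_test(tab)[1] if (tab > 0).all() else np.nan
    rows.append(
        {
            "characteristic": "female_fraction",
            "ms_mean": (ms_s.sex == "F").mean(),
            "ms_sd": np.nan,
            "hc_mean": (hc_s.sex == "F").mean() if len(hc_s) else np.nan,
            "hc_sd": np.nan,
            "p": p_sex,
        }
    )
    return pd.DataFrame(rows)
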