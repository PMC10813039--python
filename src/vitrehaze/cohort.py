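"""Synthetic cohort generator for the eye-level haze analysis.

Simulates an MS / healthy-control cohort with the covariate structure
the analysis assumes: subject-level demographics, disease covariates and
normalized brain volumes; eye-level layer thicknesses; and a log-scale
haze outcome with a shared-subject random effect that induces a
configurable inter-eye correlation.

The outcome model, on the analysis (natural-log) scale, is

    log_vh = lp(covariates) + u_subject + e_eye,
    u ~ N(0, rho * sd^2),  e ~ N(0, (1 - rho) * sd^2),

so that corr(eye1, eye2 | covariates) = rho and the total residual SD is
``residual_sd``.  Covariate effects enter the linear predictor centred
at the MS reference means, so each configured beta is exactly the
estimand of the corresponding age/sex-adjusted eye-level regression
(covariates are drawn mutually independently given group).

The configured group contrast and disability-stratum shifts are stated
as *marginal adjusted estimands* (percent differences on the haze
scale); the generator derives the structural group coefficient from
them, accounting for the group gaps in the covariate means, so an
age/sex-adjusted GEE of group on log-VH recovers the configured percent
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

EYES = ("OD", "OS")


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Covariate means/SDs default to the included study cohort (290
    patients, 85 controls); regression coefficients on the log-VH scale
    default to the reported eye-level estimates.  Brain volumes are in
    mL, thicknesses in µm, age and disease duration in years.
    """

    n_patients: int = 290
    n_controls: int = 85
    seed: int = 0

    # subject-level covariates: (mean, sd) per group
    age_ms: tuple = (51.5, 10.1)
    age_hc: tuple = (49.3, 8.2)
    female_frac_ms: float = 195 / 290
    female_frac_hc: float = 53 / 85
    duration: tuple = (17.9, 7.0)
    phenotype_weights: tuple = (200 / 290, 59 / 290, 31 / 290)  # RRMS, SPMS, PPMS
    edss_weights: tuple = (164 / 291, 64 / 291, 63 / 291)  # mild, moderate, severe
    mson_weights: tuple = (157 / 277, 81 / 277, 39 / 277)  # none, unilateral, bilateral

    ngmv_ms: tuple = (759.0, 58.4)
    ngmv_hc: tuple = (795.5, 53.3)
    nwmv_ms: tuple = (665.2, 43.8)
    nwmv_hc: tuple = (696.3, 33.8)
    lesion_ms: tuple = (12.0, 10.0)

    # eye-level layer thickness: subject (mean, sd) and within-subject eye sd
    prnfl_ms: tuple = (84.6, 14.4)
    prnfl_hc: tuple = (95.1, 7.9)
    prnfl_eye_sd: float = 5.0
    gcipl_ms: tuple = (77.5, 14.3)
    gcipl_hc: tuple = (92.2, 6.0)
    gcipl_eye_sd: float = 4.0
    inl_ms: tuple = (40.4, 3.3)
    inl_hc: tuple = (39.4, 2.9)
    inl_eye_sd: float = 1.5

    # log-VH outcome model
    beta_age: float = -0.007
    beta_duration: float = -0.009
    beta_sex_male: float = 0.014
    beta_prnfl: float = 0.004
    beta_gcipl: float = 0.006
    beta_ngmv: float = 0.001
    beta_nwmv: float = 0.001
    #: marginal age/sex-adjusted MS-vs-HC percent difference on the haze scale
    group_pct_difference: float = 9.58
    #: marginal stratum contrasts (percent, vs mild): severe -23.56 per the
    #: disability comparison; moderate derived from severe-vs-moderate -28.86
    stratum_pct_vs_mild: tuple = (0.0, 7.45, -23.56)
    #: mean haze ratio of healthy-control eyes (sets the intercept)
    hc_mean_vh: float = 0.16
    inter_eye_correlation: float = 0.6
    residual_sd: float = 0.35

    # QC emulation
    eye_qc_fail_prob: float = 0.0
    pathology_prob: float = 0.0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_controls < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if not 0 <= self.inter_eye_correlation < 1:
            raise ConfigError("inter_eye_correlation must be in [0, 1)")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd must be positive")
        for name in ("phenotype_weights", "edss_weights", "mson_weights"):
            w = getattr(self, name)
            if abs(sum(w) - 1.0) > 1e-6 or min(w) < 0:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        for name in (
            "age_ms", "age_hc", "duration", "ngmv_ms", "ngmv_hc", "nwmv_ms",
            "nwmv_hc", "lesion_ms", "prnfl_ms", "prnfl_hc", "gcipl_ms",
            "gcipl_hc", "inl_ms", "inl_hc",
        ):
            if getattr(self, name)[1] <= 0:
                raise ConfigError(f"{name} SD must be positive")
        if not 0 <= self.eye_qc_fail_prob <= 1 or not 0 <= self.pathology_prob <= 1:
            raise ConfigError("probabilities must be in [0, 1]")


#: EDSS half-point values available within each stratum
_EDSS_VALUES = {
    "mild": np.arange(0.0, 4.0, 0.5),
    "moderate": np.arange(4.0, 6.0, 0.5),
    "severe": np.arange(6.0, 8.5, 0.5),
}
_STRATA = ("mild", "moderate", "severe")


def _group_beta(cfg: CohortConfig) -> float:
    """Structural MS coefficient giving the configured marginal contrast.

    The age/sex-adjusted group model leaves layer-thickness, brain
    volume, duration and stratum effects unadjusted, so their group mean
    gaps load onto the group coefficient; subtract them from the target.
    """
    target = math.log(1.0 + cfg.group_pct_difference / 100.0)
    gap = 0.0
    gap += cfg.beta_prnfl * (cfg.prnfl_ms[0] - cfg.prnfl_hc[0])
    gap += cfg.beta_gcipl * (cfg.gcipl_ms[0] - cfg.gcipl_hc[0])
    gap += cfg.beta_ngmv * (cfg.ngmv_ms[0] - cfg.ngmv_hc[0])
    gap += cfg.beta_nwmv * (cfg.nwmv_ms[0] - cfg.nwmv_hc[0])
    # duration and stratum shifts are centred to mean zero within MS, so
    # they do not move the group contrast
    return target - gap


def _stratum_shifts(cfg: CohortConfig) -> np.ndarray:
    """Mean-zero log-scale stratum effects matching the configured
    percent contrasts vs the mild stratum."""
    raw = np.array([math.log(1.0 + p / 100.0) for p in cfg.stratum_pct_vs_mild])
    w = np.asarray(cfg.edss_weights)
    return raw - float(w @ raw)


def generate_cohort(config: CohortConfig, seed: int | None = None):
    """Simulate the cohort; returns ``(subject_table, eye_table)``.

    Two rows per subject in the eye table (OD, OS).  The eye table
    carries the true linear predictor (``lp_true``) as a sidecar column
    so parameter-recovery tests can form exact residuals; analysis code
    never reads it.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_ms, n_hc = cfg.n_patients, cfg.n_controls
    n = n_ms + n_hc
    if n == 0:
        raise ConfigError("empty cohort")

    is_ms = np.r_[np.ones(n_ms, bool), np.zeros(n_hc, bool)]
    subject_id = np.array([f"S{i:05d}" for i in range(n)])

    def pick(ms_par, hc_par):
        mean = np.where(is_ms, ms_par[0], hc_par[0])
        sd = np.where(is_ms, ms_par[1], hc_par[1])
        return rng.normal(mean, sd)

    age = pick(cfg.age_ms, cfg.age_hc)
    female_frac = np.where(is_ms, cfg.female_frac_ms, cfg.female_frac_hc)
    sex = np.where(rng.random(n) < female_frac, "F", "M")
    duration = np.where(is_ms, np.clip(rng.normal(*cfg.duration, n), 0, None), np.nan)
    phenotype = np.where(
        is_ms, rng.choice(["RRMS", "SPMS", "PPMS"], n, p=cfg.phenotype_weights), "HC"
    )
    stratum_idx = rng.choice(3, n, p=cfg.edss_weights)
    edss = np.array(
        [rng.choice(_EDSS_VALUES[_STRATA[k]]) for k in stratum_idx], dtype=float
    )
    edss = np.where(is_ms, edss, np.nan)
    mson = np.where(
        is_ms,
        rng.choice(["none", "unilateral", "bilateral"], n, p=cfg.mson_weights),
        "none",
    )
    ngmv = pick(cfg.ngmv_ms, cfg.ngmv_hc)
    nwmv = pick(cfg.nwmv_ms, cfg.nwmv_hc)
    lesion = np.where(is_ms, np.clip(rng.normal(*cfg.lesion_ms, n), 0, None), 0.0)
    pathology = rng.random(n) < cfg.pathology_prob

    subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": np.where(is_ms, "MS", "HC"),
            "phenotype": phenotype,
            "age": age,
            "sex": sex,
            "disease_duration": duration,
            "edss": edss,
            "ngmv_ml": ngmv,
            "nwmv_ml": nwmv,
            "nbv_ml": ngmv + nwmv,
            "lesion_ml": lesion,
            "mson": mson,
            "pathology": pathology,
        }
    )

    # eye-level thickness: subject mean + per-eye deviation
    prnfl_subj = pick(cfg.prnfl_ms, cfg.prnfl_hc)
    gcipl_subj = pick(cfg.gcipl_ms, cfg.gcipl_hc)
    inl_subj = pick(cfg.inl_ms, cfg.inl_hc)

    sd = cfg.residual_sd
    rho = cfg.inter_eye_correlation
    u = rng.normal(0.0, math.sqrt(rho) * sd, n)

    beta_ms = _group_beta(cfg)
    shifts = _stratum_shifts(cfg)
    # anchor the intercept so the marginal HC mean haze ratio is hc_mean_vh
    # (lognormal mean correction uses the residual variance; the small extra
    # variance contributed by covariate spread is neglected)
    hc_dev = (
        cfg.beta_age * (cfg.age_hc[0] - cfg.age_ms[0])
        + cfg.beta_sex_male * ((1 - cfg.female_frac_hc) - (1 - cfg.female_frac_ms))
        + cfg.beta_prnfl * (cfg.prnfl_hc[0] - cfg.prnfl_ms[0])
        + cfg.beta_gcipl * (cfg.gcipl_hc[0] - cfg.gcipl_ms[0])
        + cfg.beta_ngmv * (cfg.ngmv_hc[0] - cfg.ngmv_ms[0])
        + cfg.beta_nwmv * (cfg.nwmv_hc[0] - cfg.nwmv_ms[0])
    )
    intercept = math.log(cfg.hc_mean_vh) - 0.5 * sd**2 - hc_dev

    male = (sex == "M").astype(float)
    subj_lp = (
        intercept
        + beta_ms * is_ms
        + cfg.beta_age * (age - cfg.age_ms[0])
        + cfg.beta_sex_male * (male - (1.0 - cfg.female_frac_ms))
        + np.where(is_ms, cfg.beta_duration * (np.nan_to_num(duration) - cfg.duration[0]), 0.0)
        + cfg.beta_ngmv * (ngmv - cfg.ngmv_ms[0])
        + cfg.beta_nwmv * (nwmv - cfg.nwmv_ms[0])
        + np.where(is_ms, shifts[stratum_idx], 0.0)
    )

    eye_rows = []
    for e_idx, eye in enumerate(EYES):
        prnfl = np.clip(prnfl_subj + rng.normal(0, cfg.prnfl_eye_sd, n), 1, None)
        gcipl = np.clip(gcipl_subj + rng.normal(0, cfg.gcipl_eye_sd, n), 1, None)
        inl = np.clip(inl_subj + rng.normal(0, cfg.inl_eye_sd, n), 1, None)
        lp = (
            subj_lp
            + cfg.beta_prnfl * (prnfl - cfg.prnfl_ms[0])
            + cfg.beta_gcipl * (gcipl - cfg.gcipl_ms[0])
        )
        log_vh = lp + u + rng.normal(0.0, math.sqrt(1 - rho) * sd, n)
        mson_eye = np.where(
            mson == "bilateral",
            "affected",
            np.where(
                mson == "unilateral",
                np.where(e_idx == (np.arange(n) % 2), "affected", "fellow"),
                "none",
            ),
        )
        eye_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "eye": eye,
                    "vh_ratio": np.exp(log_vh),
                    "log_vh": log_vh,
                    "prnfl_um": prnfl,
                    "gcipl_um": gcipl,
                    "inl_um": inl,
                    "qc_pass": rng.random(n) >= cfg.eye_qc_fail_prob,
                    "mson_eye": mson_eye,
                    "lp_true": lp,
                }
            )
        )
    eyes = (
        pd.concat(eye_rows, ignore_index=True)
        .sort_values(["subject_id", "eye"], kind="stable")
        .reset_index(drop=True)
    )
    return subjects, eyes
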