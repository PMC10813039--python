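"""Simulate an eye-level cohort and recover the generating regression
coefficients with the exchangeable GEE.

Each subject contributes two eyes whose log haze scores share a subject
random effect (inter-eye correlation 0.6 by default); the GEE with an
exchangeable working correlation accounts for this clustering and its
sandwich standard errors stay honest.
"""

import vitrehaze as vz

cfg = vz.CohortConfig(n_patients=2000, n_controls=600)
subjects, eyes = vz.generate_cohort(cfg, seed=7)
d = eyes.merge(subjects, on="subject_id")
d["male"] = (d.sex == "M").astype(float)
ms = d[d.group == "MS"]

targets = {"age": cfg.beta_age, "disease_duration": cfg.beta_duration,
           "prnfl_um": cfg.beta_prnfl, "gcipl_um": cfg.beta_gcipl,
           "ngmv_ml": cfg.beta_ngmv, "nwmv_ml": cfg.beta_nwmv}

print(f"{'covariate':18s} {'estimate':>9s} {'95% CI':>22s} {'generating':>11s}")
for cov, target in targets.items():
    adjust = ["male"] if cov == "age" else ["age", "male"]
    fit = vz.fit_gee(ms, "log_vh", [cov] + adjust, "subject_id")
    ci = f"[{fit.ci_low[cov]:+.4f}, {fit.ci_high[cov]:+.4f}]"
    print(f"{cov:18s} {fit.params[cov]:+9.4f} {ci:>22s} {target:+11.4f}")

fit_rho = vz.fit_gee(ms, "log_vh", ["age", "male"], "subject_id")
print(f"\nworking inter-eye correlation rho_hat = {fit_rho.rho_hat:.3f}")
print("(larger than the structural 0.6: residuals of the age-only model also")
print("contain the subject-level covariate effects left unmodelled)")

d["ms_ind"] = (d.group == "MS").astype(float)
fit_g = vz.fit_gee(d, "log_vh", ["ms_ind", "age", "male"], "subject_id")
print(f"\nadjusted MS-vs-control haze difference: "
      f"{vz.group_contrast(fit_g, 'ms_ind'):+.2f}% (p = {fit_g.p_values['ms_ind']:.3f})")
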