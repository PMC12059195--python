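"""Simulate daytime PSI data from a known mixed-effects model and refit it.

The model regresses the Physiological Strain Index on outdoor WBGT, sex,
their interaction, daily MVPA, previous-night sleep, BMI and fat-mass
percentage, with a participant random intercept, fitted by maximum
likelihood on 06:30-18:30 observations.
"""

from heatwear.config import default_config
from heatwear.models import fit_psi_wbgt_lme
from heatwear.synthetic import simulate_psi_lme_dataset

truth = default_config()["lme_truth"]
betas = {k: truth[k] for k in ("beta0", "sex_male", "wbgt", "wbgt_sex",
                               "mvpa", "sleep", "bmi", "fat_mass")}
df, _ = simulate_psi_lme_dataset(betas, n_participants=48,
                                 obs_per_participant=144,
                                 random_intercept_sd=truth["random_intercept_sd"],
                                 residual_sd=truth["residual_sd"], seed=1)
fit = fit_psi_wbgt_lme(df)

print(f"{len(df)} daytime observations, {df['participant_id'].nunique()} "
      "participants\n")
shown = {"wbgt": "WBGT slope", "male": "sex (male)",
         "wbgt:male": "WBGT x male", "mvpa_hours": "MVPA (h)"}
print(f"{'term':14s} {'truth':>7s} {'estimate':>9s}   95% CI")
for term, label in shown.items():
    tv = {"wbgt": betas["wbgt"], "male": betas["sex_male"],
          "wbgt:male": betas["wbgt_sex"], "mvpa_hours": betas["mvpa"]}[term]
    lo, hi = fit.ci(term)
    print(f"{label:14s} {tv:7.2f} {fit.estimate(term):9.3f}   "
          f"[{lo:6.3f}, {hi:6.3f}]")
print(f"\nrandom-intercept SD {fit.random_intercept_sd:.3f} "
      f"(truth {truth['random_intercept_sd']}), residual SD "
      f"{fit.residual_sd:.3f} (truth {truth['residual_sd']})")
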