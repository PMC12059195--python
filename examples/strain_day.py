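"""Compute one participant's heat-strain day: baselines, reserves, PSI.

Cardiac strain is the heart-rate elevation above the resting minimum as a
percentage of the heart-rate reserve (age-predicted peak minus resting HR);
thermal strain is the core-temperature elevation above its nadir as a
percentage of the reserve to the 39.5 C critical temperature. The
Physiological Strain Index weights each component by 5 onto a 0-10 scale.
"""

from heatwear.pipeline import run_qc, run_strain
from heatwear.synthetic import CohortSpec, simulate_study

spec = CohortSpec.default(seed=7, n_pairs=2, n_days=7)
study = simulate_study(spec, include_gps=False)
qc = run_qc(study)
sr = run_strain(study, qc)

# pick a participant whose HR and CBT recordings survived (a device can
# fail outright, mirroring field losses)
pid = sorted(sr.reserves)[0]
res = sr.reserves[pid]
print(f"{pid}: RHR {res.rhr:.1f} bpm, predicted peak {res.predicted_peak:.1f} bpm"
      f" -> HR reserve {res.hrr:.1f} bpm")
print(f"      resting CBT {res.resting_cbt:.2f} C -> thermal reserve "
      f"{res.cbt_reserve:.2f} C")

df = sr.per_epoch[pid]
row = sr.per_participant.set_index("participant_id").loc[pid]
print(f"\n5-min epochs: {len(df)};  mean cardiac strain "
      f"{row['mean_cardiac_pct']:.1f}%,  mean thermal strain "
      f"{row['mean_thermal_pct']:.1f}%,  mean PSI {row['mean_psi']:.2f}")
peak = df.loc[df["psi"].idxmax()]
print(f"peak PSI {peak['psi']:.2f} at {peak['timestamp']} "
      "(afternoon heat plus activity)")
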