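"""Generate a small synthetic wearable cohort and look at what it contains.

The generator emulates a paired field deployment: couples of subsistence
farmers wear actigraphy for 14 days plus one 24-h heart-rate/core-temperature
day, while a logger records indoor WBGT in each household. Every latent
quantity (resting physiology, sleep windows, injected gaps and artifacts)
is retained in a truth ledger.
"""

from heatwear.synthetic import CohortSpec, simulate_study

spec = CohortSpec.default(seed=42, n_pairs=3, n_days=7)
study = simulate_study(spec)

print(f"cohort: {len(study.profiles)} participants in "
      f"{len(study.households)} households")
for pid, prof in study.profiles.items():
    print(f"  {pid}: {prof.sex:6s} age {prof.age}  BMI {prof.bmi}  "
          f"true RHR {study.truth.resting_hr[pid]:.1f} bpm  "
          f"true resting CBT {study.truth.resting_cbt[pid]:.2f} C")

gaps = study.truth.gap_frame()
arts = study.truth.artifact_frame()
print(f"\ninjected degradation: {len(gaps)} gap/failure events, "
      f"{len(arts)} implausible-value artifacts")
print("Each artifact lies outside the plausibility bounds, so the QC stage "
      "can be scored against this ledger.")
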