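"""Quality-control and feasibility accounting for a simulated deployment.

Usable data are whatever survives the plausibility filters (HR within
[40 bpm, age-predicted max], CBT within [35, 42] C). Availability is the
share of participants with any usable recording per device; completeness
is the usable share of each device's intended recording time.
"""

from heatwear.pipeline import run_qc
from heatwear.synthetic import CohortSpec, simulate_study

spec = CohortSpec.default(seed=3, n_pairs=24, n_days=14)
study = simulate_study(spec)
qc = run_qc(study)

print(f"QC: {qc.counts['records_in']} HR/CBT samples in, "
      f"{qc.counts['records_rejected']} rejected as implausible")
print("\nFeasibility by device (availability %, completeness median [Q1-Q3]):")
for _, r in qc.feasibility.iterrows():
    print(f"  {r['device']:12s} avail {r['availability_pct']:5.1f}%   "
          f"median {r['completeness_median']:5.1f}% "
          f"[{r['completeness_q1']:.1f}-{r['completeness_q3']:.1f}]")
print("\nActigraphy availability is the weak spot by design; GPS wear time "
      "drives the widest completeness spread.")
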