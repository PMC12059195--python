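# Methods

This note documents the models, conventions and design choices behind
`heatwear`, in the order data flow through the pipeline.

## Time, epochs and canonical formats

All timestamps are naive local time: the study design clock-aligns every
device to local time, so timezone arithmetic and DST handling are out of
scope. Gaps are absent rows — a series never stores NaN. Numeric streams
are averaged onto a 5-minute epoch grid before strain computation (the
epoch length is configuration, `strain.epoch_min`); the epoch label is the
epoch *start*, which keeps gap bookkeeping unambiguous, and an epoch with
no samples is absent, never imputed. The day window is the half-open
interval **[06:30, 18:30)** — the same restriction the daytime strain model
uses — so the day/night split is an exact partition. The canonical table
format is CSV with ISO-8601 second-precision timestamps and `.` decimals,
chosen so write/read round trips are lossless at stated precision; GPS
tracks use GPX 1.1 with 7-decimal coordinates.

## Plausibility filtering and feasibility

Usable data are what remain after removing implausible values: heart rate
below 40 bpm or above the participant's age-predicted maximum
(208 − 0.7·age bpm), and CBT outside 35–42 °C. Bounds are inclusive —
"below 40" and "outside the range" exclude only values strictly beyond the
bounds, so exactly 40 bpm or exactly 35.0/42.0 °C is kept. Unparseable rows
are rejected at load time with their row index and count against
completeness. GPS and WBGT streams carry no physiological plausibility
rule; only structural validity (coordinate ranges, timestamp order) is
enforced.

Completeness credits each sample with one nominal sampling interval of
coverage and takes the union of those intervals, so denser-than-nominal or
irregular sampling never double-counts time; the ratio to the device's
intended duration is capped at 100%. Availability is the share of units
(participants, or households for the indoor logger) with at least one
usable recording. Distribution summaries use linear-interpolation
quartiles (numpy's default, "type 7"); the convention is configurable
because none is canonical at n ≈ 48.

## Strain and the PSI

Baselines are minima of the epoch-averaged clean series over the full
24-h wearing period (epoch averaging suppresses residual single-sample
artifacts; a per-day option exists for longer deployments). Reserves are
HRR = HRmax − RHR and CBT reserve = 39.5 °C − T₀; the Tanaka coefficients
(208, −0.7) and the 39.5 °C critical temperature are configuration, not
constants in code. Per epoch, cardiac strain, thermal strain and
PSI = 5·(cardiac + thermal)/100 satisfy the additive identity exactly; PSI
is clamped to [0, 10] by default because field heart rates can exceed the
age-predicted peak, and the unclamped components are always retained.
Epochs present in only one stream keep their single component and are
flagged incomplete; they are excluded from PSI means. The coefficient of
variation of HR uses the sample (n−1) standard deviation. Sleep efficiency
is averaged per night, not as a ratio of means — with variable night
lengths the two differ, and only per-night averaging is consistent with
the reported summary levels this package is calibrated to.

## Activity and sleep

Intensity classification uses strictly increasing cut-points on epoch
acceleration magnitude with left-closed bins ([0,c₁) sedentary, [c₁,c₂)
light, [c₂,c₃) moderate, [c₃,∞) vigorous; defaults 0.08/0.30/0.90
magnitude units). The cut-points are mandatory configuration: the upstream
actigraphy toolchain's thresholds are cited but not printed in the source
material, so the defaults here are package choices aligned with the
synthetic generator's state bins. Sleep detection is a deliberately simple
threshold-run rule — the longest sub-cut-point run inside the 20:00–10:00
night window, bridging active bouts of at most 20 epochs, with asleep
epochs below a stricter threshold (0.02) and windows containing no asleep
epoch discarded — because the study's own sleep algorithm is delegated to a
vendor toolchain it does not restate; the generator's truth ledger is the
accuracy reference, and on generated data detection recovers the ledger
epoch-for-epoch. Daily distance falls back to steps × stride (default
0.78 m) when no GPS summary covers the day.

## Geolocation

Great-circle distances use the Haversine formula on the IUGG mean Earth
radius 6371.0088 km. Farm parcels are modelled as circles of the stated
area (the source gives areas, not polygons): radius = √(area·4046.8564224/π),
62.2 m for the 3-acre buffered farm. Label precedence is home > farm >
elsewhere where fences overlap (conservative home-time accounting), each
inter-fix interval is attributed to the earlier fix's label with no
interpolation, and gaps longer than 10 minutes are counted as unobserved
rather than guessed.

## Mixed-effects models

Both models use a participant random intercept and maximum-likelihood
estimation via statsmodels `MixedLM`. Fixed-effect confidence intervals use
the normal approximation (no degrees-of-freedom correction is stated in the
source material, and at ~48 groups the difference is small). Covariates
enter on their natural scale so coefficients are directly comparable across
studies. The sex-comparison model is provided both in its plain printed
form and with an optional WBGT adjustment (default: plain). The optimizer
is BFGS with a Powell fallback: L-BFGS can park the random-intercept
variance on the boundary, which degrades between-participant fixed effects.
"Previous night sleep" is the total sleep time of the night ending on the
observation's date.

## The synthetic cohort generator

The generator defines the study conditions; its defaults live in one
documented file (`heatwear/data/defaults.yaml`) and the code contains no
magic physiology numbers.

* **Cohort.** 24 male–female pairs (one per household), ages uniform on
  20–45, sex-specific anthropometry; BMI is derived from height and weight.
* **Environment.** WBGT is a single-harmonic sinusoid plus Gaussian noise
  at 10-minute cadence: outdoor mesor 19.3 °C, amplitude 5 °C, peak 14:30,
  so hourly maxima peak in the 14:00–15:00 bin; indoor mesor 20.5 °C with a
  smaller, lagged amplitude and a 0.3 °C between-household offset SD. The
  mesors equal the daily means the pipeline is expected to reproduce.
* **Physiology.** HR = RHR + uplift + noise, floored at the participant's
  true RHR (CBT analogous around its baseline). The uplift mixes a
  circadian lobe (a positive-part cosine, zero in the small hours), the
  activity intensity implied by the actigraphy state ledger, and outdoor
  WBGT excess over 18 °C, with mixing weights 0.5/0.3/0.2 (0.7/0.2/0.1 for
  CBT). The mix is rescaled per participant so the time-mean cardiac and
  thermal strain against the true baselines equal sex-specific targets
  (34.86%/29.48% women, 30.95%/27.28% men) — calibration by construction
  rather than by tuning. Single-harmonic shapes are a modelling choice; the
  source shows empirical diurnal curves without a functional form. The
  reported summary tables this calibration draws on are not jointly
  attainable under the stated strain definitions (their printed mean HR,
  peak HR and relative HR change are mutually inconsistent), so the
  generator reproduces the strain marginals — relative changes, PSI,
  resting values — and lets the raw HR mean fall where the definitions put
  it.
* **Activity and sleep.** 60-s epochs with per-state magnitudes drawn
  strictly inside the classifier's cut-point bins, so classification
  recovers the state ledger exactly; nightly in-bed windows with short wake
  bouts sized to the target efficiency (bouts stay below the detector's
  bridge length, and a buffer of light activity brackets each window, so
  recovery is exact by design). MVPA is placed in morning and early
  afternoon blocks, before the outdoor WBGT peak.
* **GPS.** A commute day: home → 1.65 km walk → 3.5 h farm dwell → walk
  home, 1-minute fixes over 22 h, cumulative length 3.3 km. Dwell fixes are
  stationary by default (fix noise is configurable), so route length is
  exact and truth labels are the geofence labels of the noiseless
  positions.
* **Missingness and artifacts.** Whole-recording failures (actigraphy 12%,
  ECG/GPS 4%, CBT and WBGT 0% — devices reported only as ">94% available"
  default to the 95–100% band), gap intervals with Beta-distributed total
  fraction (GPS: Beta(4.2, 15.8), centring completeness near 79% with the
  reported spread), and implausible-value artifacts at 0.5% of samples
  drawn just *outside* the plausibility bounds (e.g. HR uniform on
  [20, 39]) so filter recovery is unambiguous. Every removal and insertion
  is ledgered.
* **Model-truth data.** `simulate_psi_lme_dataset` draws PSI exactly from
  the daytime mixed model. Of its default coefficient vector, the WBGT,
  sex, WBGT×sex and MVPA entries are the published estimates (0.32, 5.33,
  −0.27, −0.16); the intercept, sleep, BMI and fat-mass entries and the
  variance components (random-intercept SD 0.5, residual SD 0.8) are
  synthetic defaults chosen once to keep simulated PSI on its 0–10 scale,
  as the full published table is not available in the source text.
* **Randomness.** One root seed with per-participant, per-device
  `SeedSequence` substreams: enlarging the cohort never perturbs existing
  participants' draws.

**What the generator does not emulate:** raw ECG waveforms and R-peak
detection, device-rate triaxial acceleration, GPS fix error beyond white
noise, weather-station-to-WBGT estimation, nonwear, and behavioural
feedback between heat and activity. Passing recovery tests therefore show
that the analysis stages are correct and internally consistent at the
study's scale and noise levels — not that they are robust to every artifact
real devices produce.

## Problem sizes

The default test and reproduction runs use the study's own scale — 48
participants, 14-day actigraphy, one 24-h HR/CBT day at 1-minute cadence —
with 20 seed replicates for cohort-level averages and 50 replicates for
model-recovery rates; smaller cohorts (2–3 pairs, a few days) are used
where a property does not depend on scale.

## Known limitations

Sleep detection is tuned to the generator's structure and would need
validation before use on real actigraphy. The completeness denominator
assumes the intended duration is wholly inside the deployment window.
Geofences are circular; irregular parcels are out of scope. Likert and
social-experience outputs summarise responses but do not model them. The
survey generator uses a single sentiment distribution rather than the
device- and sex-specific patterns a real cohort shows.
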