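# Methods

## Model structure

`edsim` simulates one ED as a discrete-event system. The event calendar
pops pending events in `(time, kind-priority, insertion order)` order; the
fixed kind-priority table makes same-instant races deterministic and
decides the one boundary case that matters clinically: resource-freeing
events and the bed-assignment scans they trigger are processed before
reneging deadlines, so a patient offered a bed at exactly their waiting
tolerance stays. Replications are independent; each derives per-purpose
random substreams (arrivals, durations, tolerances, routing, boarding,
travel) from the master seed, so a `(config, seed)` pair reproduces the
event log byte-for-byte.

### Arrivals

A non-homogeneous Poisson process per acuity with piecewise-constant hourly
intensity, generated interval-wise (a Poisson count per hourly step with
uniformly scattered times), which is exact for step intensities; a thinning
generator is kept as a test oracle. The daily profile is
`daily_mean × acuity_fraction × normalized 24-hour shape`. The packaged
shape has an overnight trough (~0.2× the daily mean rate), a morning rise,
and an evening peak (~1.6×), consistent with published hourly ED arrival
curves; it is fully overridable per acuity.

### Service and delay times

All durations are independent Gamma variables specified by (mean, variance)
with shape = mean²/var and scale = var/mean. Variance 0 is accepted as a
degenerate point mass — deterministic pipelines are essential test
fixtures — and mean 0 as an instantaneous step. Unless a profile overrides
it, dispersion defaults to a coefficient of variation of 0.5. Provider
room-to-room travel is exponential with a constant mean per provider class
(the time-modulation hook exists but defaults to off). Nurse response is
folded into the Gamma nurse-assessment delay rather than drawn as a
separate travel time.

### Flow rules

- ESI-1 arrivals take a trauma bed immediately, preempting the
  lowest-acuity, most-recently-bedded occupant who is still in active
  treatment (never another ESI-1, never a dispositioned patient). The
  displaced patient keeps completed milestones, re-queues at the head of
  their acuity class, and resumes the *remaining* portion of any
  interrupted assessment once re-bedded; their reneging clock does not
  restart. Admitted patients boarding in a trauma bay are relocated to a
  free plain MTA bed at disposition when one exists, keeping resuscitation
  capacity available.
- ESI-2 patients bypass triage with configurable probability (default 0.2);
  bypassing skips the triage delay but not the bed queue — they wait at the
  head of the queue rather than preempting.
- The waiting room is ordered by (acuity, arrival time). ESI-2/3 may use
  plain MTA beds and trauma bays as overflow; ESI-4/5 prefer the Fast Track
  when one is configured and never hold a patient of acuity 1–3. Patients
  never switch between the MTA and FT once assigned. The triage+registration
  parameter is a single pooled Gamma delay with no capacity constraint.
- A bedded patient holds `1/ratio(acuity)` of a nurse for the full bed stay.
  The bed scan stops at the first patient blocked purely by nursing (the
  nurse pool is global; skipping ahead would starve high-acuity patients).
  Boarded patients hold `boarding_nurse_factor ×` their treatment-phase
  share (default 1.0; the packaged profiles use 0.5, reflecting the lighter
  monitoring of stable patients awaiting transfer — with full demand the
  academic environment becomes nurse-limited rather than bed-limited,
  contradicting its intended dynamics).
- Treatment: initial physician (or PA, in the FT) assessment, then test
  cycles — labs ordered with probability `p_lab`, imaging with `p_imaging`;
  results arrive after the maximum of the drawn turnaround times and
  trigger a second provider seize for review (a shorter assessment draw);
  further cycles continue with probability `cycle_continuation`, capped at
  `max_cycles` (default 3). Providers are pooled, not assigned to patients.
- Disposition draws admit with the acuity admit rate. Discharges leave
  after a discharge-processing delay (instructions, paperwork, room
  turnover); admits block their bed for a Gamma boarding draw that is
  acuity- and time-invariant.

### Staffing

Head counts may be constant or a 24-element per-hour duty schedule. The
packaged profiles schedule physicians (61 physician-hours/day nationally,
66 in the academic profile, with the listed head count as the daytime
maximum); PA and nurse staffing are constant. When a schedule steps down,
capacity recovers as providers finish their current assessment.

## Metrics

Summary statistics use patients arriving inside the window after a 2-day
warm-up; patients still in the ED at the horizon are censored — counted as
arrivals but excluded from time means. The LWBS denominator is all
arrivals. `patients_per_doctor_hour` divides patients whose first provider
contact was a physician by scheduled physician-hours.
`patients_per_bed_year` annualizes total arrival volume (including LWBS)
per bed, the reading consistent with the published per-bed benchmarks. The
census replays exact bed-occupancy segments (treatment and boarding
separately, with the nursing fraction attached), so preemption gaps are
represented correctly; `replay_audit` re-derives all capacity and
conservation invariants from the log alone.

## Calibrated environments

Bed/staff counts, arrival volume, the 1:4 nurse ratio, the 3.5 h mean
tolerance, assessment means, turnaround times, admit rates, and boarding
means are fixed published inputs. The remaining parameters are free and
were calibrated once against the published throughput benchmarks, then
frozen:

- **Acuity mix** — national (1, 9, 40, 35, 15)%; academic (2, 24, 46, 19,
  9)%, shifted toward ESI-2/3 as is typical of academic centers.
- **Nurse ratios** — (1:1, 1:4, 1:4, 1:4, 1:4) for ESI-1..5: the published
  overall 1:4 with one-to-one nursing for resuscitation patients only.
- **Tolerances** — per-acuity means proportional to (6, 5, 4.1, 3.0, 2.4)
  nationally and (5, 4.6, 4.0, 3.3, 3.0) academically (sicker patients
  hold out longer), scaled so the arrival-weighted mean is exactly 3.5 h;
  CV 0.26 / 0.22. Only the mean is published; the tight dispersion makes
  reneging a tail phenomenon, which is what reconciles hour-scale mean
  waits with single-digit LWBS rates.
- **Complexity** — per-acuity `p_lab`/`p_imaging` from ~0.95/0.90 (ESI-1)
  down to 0.25/0.10 (ESI-5); cycle-continuation 0.50–0.55 for ESI-1..3,
  lower for ESI-4/5.
- **Triage+registration** — mean 15 min national, 30 min academic.
- **Discharge processing** — mean 30 min national, 85 min academic; the
  longer academic value is forced by the arithmetic of the published
  disposition-to-exit gap once the boarding mean and admit rate are fixed.
- **Review assessment** 6.5 / 5 min; **physician travel** 1.25 / 1 min;
  **ESI-2 bypass** 0.2.

With these frozen profiles, ten 30-day replications reproduce every
published validation output within two replication standard deviations in
both environments (the acceptance suite asserts exactly this), and the
numerical-experiment signatures hold: one added national physician cuts
mean LOS by ~1 h with no comparable gain from a second; national physicians
are essentially never idle from noon to midnight; academic ESI-3 mean LOS
exceeds 6 h; admit LOS is monotone in the boarding mean while national
discharge LOS and LWBS stay nearly flat.

## Numerical and design choices

- Floating-point nursing comparisons use a 1e-9 tolerance; NHPP outputs are
  forced strictly increasing by nudging ties (probability-zero events).
- Ten replications × 30 days with a 2-day warm-up is the standard run; a
  replication of either profile takes on the order of a second, and the
  full acceptance recomputation under a minute on one CPU.
- The queueing kernel is validated by reduction: one bed, zero-delay steps,
  stationary arrivals and shape-1 Gamma service collapse the bed queue to
  M/M/1 (and three beds to M/M/3), checked against the Erlang-C closed form
  within four batch-mean standard errors.
- Per-replication seeds are derived as `(seed·100003 + 7919·rep) mod 2³¹−1`;
  substream labels are hashed with CRC-32 into independent SeedSequence
  spawn keys.

## What the generator does and does not emulate

The synthetic environments reproduce aggregate arrival intensity, acuity
mix, and duration means/variances, but not day-of-week or seasonal
structure, correlated patient complexity (tests are drawn independently per
cycle), physician-patient continuity, time-dependent boarding, ambulance
diversion, or triage-capacity queues. Passing tests therefore demonstrate
internal consistency and fidelity to the published benchmark regime, not
predictive accuracy for any specific hospital; site-specific use requires
refitting the free parameters above to local data.

## Known limitations

- Staff counts are interpreted as simultaneous on-duty head counts (with
  the optional hourly schedule), not shift totals; the published sources do
  not say which is meant.
- LWBS depends only on waiting time; boarding draws are acuity- and
  time-invariant; hospital-side discharge timing is not modeled.
- The nurse model is fractional occupancy, so brief nursing interventions
  are not separate queueing events.
- Preemption semantics (suspend/resume with retained progress) are one
  defensible reading of trauma-bay preemption; alternatives (restart, or
  transfer to another bed mid-treatment) are not implemented.
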