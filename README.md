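# edsim — discrete-event simulation of emergency-department patient flow

`edsim` is a configurable discrete-event model of a hospital-based Emergency
Department (ED), built for ED and hospital managers, operations researchers,
and health-services modelers who want to quantify the impact of operational
changes — extra staff, Fast Track pathways, shorter boarding times — before
implementing them.

## The model

Patients arrive by a non-homogeneous Poisson process with an hourly
(piecewise-constant) intensity λ_a(t), one intensity per Emergency Severity
Index acuity a ∈ {1..5} (1 = most acute). Routing is acuity-streamed:

- **ESI-1** go straight to a trauma/resuscitation bed in the Main Treatment
  Area (MTA), preempting the lowest-acuity occupant if none is free.
- A configurable fraction of **ESI-2** bypass triage; everyone else completes
  a Gamma-distributed triage+registration step and waits for a bed.
- Waiting patients are selected by **(acuity, arrival time)**; each carries a
  waiting tolerance T ~ Gamma with acuity-dependent mean, and leaves without
  being seen (**LWBS**, queueing-theoretic reneging) if no bed arrives within
  T of the door.
- Bedded patients hold an acuity-dependent **fraction of a nurse** for their
  whole stay; a bed cannot be filled without free nursing capacity, so a
  nursing shortage manifests as a lack of usable beds.
- Treatment is a cycle: a pooled provider (physicians in the MTA, physician
  assistants in the Fast Track, both with exponential travel times) performs
  an assessment, may order labs and/or imaging (Gamma turnaround times), and
  reviews results when they return, possibly ordering further cycles.
- Disposition is admit (probability = acuity admit rate) or discharge.
  Discharges exit after a processing delay; **admits board**, blocking their
  bed for a Gamma boarding delay until a hospital bed is free.

All service and delay durations are independent Gamma random variables
parameterized by mean and variance — the natural choice when only central
tendencies are known. Every random draw flows through labelled, seeded
substreams, so identical `(config, seed)` runs are byte-for-byte identical.

Two calibrated environments ship with the package:

| Input                    | `national` | `academic` |
|--------------------------|-----------:|-----------:|
| MTA / FT beds            | 32 / 0     | 41 / 6     |
| Physicians / PAs / nurses| 3 / 0 / 8  | 4 / 1 / 13 |
| Mean arrivals per day    | 155        | 195        |
| Admit rate               | 12.8%      | 25.8%      |
| Mean boarding delay      | 1.63 h     | 4.43 h     |
| Lab / imaging turnaround | 30 / 75 min| 45 / 90 min|

The national environment is **provider-limited** (physicians are saturated
from noon to midnight); the academic environment is **bed-limited** (beds,
amplified by boarding, are the binding constraint). The simulation
reproduces both regimes and their opposite responses to interventions.

## Worked example

```python
import edsim

cfg = edsim.builtin_profile("national")
summaries, logs = edsim.run_many(cfg, seed=1, days=30, replications=10)
print(edsim.aggregate_replications(summaries).round(3))
```

```
                              mean      sd
n_arrivals                4652.100  89.118
n_admits                   593.600  21.767
n_discharges              3841.100  58.974
n_lwbs                     184.900  42.655
n_censored                  32.500   5.339
lwbs_rate                    3.962   0.855
door_to_doctor               1.105   0.056
door_to_disposition          3.073   0.073
door_to_exit                 3.724   0.075
patients_per_doctor_hour     2.434   0.030
patients_per_bed_year     1768.767  33.884
```

Each row aggregates ten simulated 30-day months: about 155 arrivals/day, an
LWBS rate near 4%, a mean door-to-doctor time of 1.1 h, a mean length of
stay (door-to-exit) of 3.7 h, and roughly 2.4 patients treated per physician
per staffed hour. The `sd` column is month-to-month variability.

Scenario comparison with common random numbers:

```python
base = edsim.identity_scenario(cfg, "base")
plus = edsim.add_resources(cfg, d_physicians=1)
res = edsim.run_batch([base, plus], days=30, replications=10, seed=1)
los = {k: v["aggregate"].loc["door_to_exit", "mean"] for k, v in res.items()}
# {'base': 3.72, 'national+1md+0bed+0rn': 2.75}  -> ~1 hour shorter stays
```

In the provider-limited national ED one extra physician cuts mean length of
stay by about an hour; a second physician adds almost nothing, and the same
intervention barely moves the bed-limited academic ED. `edsim.sweep_boarding`
and `edsim.make_fast_track` explore the other intervention families, and
`edsim.census` returns the minute-by-minute patient-location and
idle-resource series behind these dynamics.

The same functionality is available from the shell:

```bash
edsim run --config academic --days 30 --replications 10 --seed 1 --out out/
edsim scenario add-resources --config national --physicians 1
edsim sweep boarding --config academic --factors 0.25,0.5,1.0,1.5
```

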