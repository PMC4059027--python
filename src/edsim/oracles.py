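"""Independent validators and hand-checkable fixtures for the test suite.

These deliberately avoid the simulation kernel's own code paths: the M/M/c
expected wait comes from the Erlang-C closed form, arrival processes can be
cross-checked against a thinning generator, calendar ordering against a
brute-force sort, and full replication logs are re-audited by replaying the
recorded intervals against every conservation/ordering/capacity invariant.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ACUITIES, DurationSpec, EDConfig, ComplexityModel, AcuityComplexity
from .engine import KIND_PRIORITY
from .flow import ADMIT, DISCHARGE, LWBS, EventLog
from .metrics import census

__all__ = [
    "mm_c_wait",
    "erlang_c_wait_probability",
    "sample_nhpp_thinning",
    "calendar_sort_oracle",
    "replay_audit",
    "degenerate_fixture",
]


def erlang_c_wait_probability(lam: float, mu: float, c: int) -> float:
    """P(wait > 0) in an M/M/c queue (Erlang-C formula)."""
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError(f"unstable queue: rho = {rho} >= 1")
    term = sum(a**k / math.factorial(k) for k in range(c))
    top = a**c / (math.factorial(c) * (1 - rho))
    return top / (term + top)


def mm_c_wait(lam: float, mu: float, c: int) -> float:
    """Expected queue wait (minutes) in an M/M/c queue.

    ``lam`` in arrivals/min, ``mu`` in services/min per server.  Requires
    rho = lam/(c*mu) < 1.
    """
    if lam == 0:
        return 0.0
    return erlang_c_wait_probability(lam, mu, c) / (c * mu - lam)


def sample_nhpp_thinning(hourly_rate, horizon_hours: float, stream) -> np.ndarray:
    """Thinning-based arrival generator (oracle for the interval method).

    Generates a homogeneous Poisson process at the profile maximum and
    accepts each point with probability rate(t)/max-rate.  Returns minutes.
    """
    rate = np.asarray(hourly_rate, dtype=float)
    lam_max = rate.max()
    if lam_max == 0:
        return np.empty(0)
    rng = stream.rng
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= horizon_hours:
            break
        if rng.random() < rate[int(t) % 24] / lam_max:
            out.append(t * 60.0)
    return np.asarray(out)


def calendar_sort_oracle(entries) -> list:
    """Expected pop order for (time, kind, seq) triples: brute-force sort."""
    return sorted(entries, key=lambda e: (e[0], KIND_PRIORITY[e[1]], e[2]))


# ---------------------------------------------------------------------------
# Replay audit
# ---------------------------------------------------------------------------

def replay_audit(log: EventLog, resolution: float = 1.0) -> list[str]:
    """Replay a replication log against every invariant; return violations.

    Checks per-patient timestamp monotonicity, disposition consistency
    (LWBS iff never bedded, waited at least their tolerance), patient-count
    conservation, bed/nurse capacity at every sample instant, and agreement
    between the location census and an independent in-system count.
    """
    v: list[str] = []
    cfg = log.cfg
    n_done = {ADMIT: 0, DISCHARGE: 0, LWBS: 0}
    n_censored = 0

    for p in log.patients:
        stamps = [("door", p.door), ("triage_done", p.triage_done),
                  ("bed", p.bed_time), ("first_doctor", p.first_provider),
                  ("disposition", p.dispo_time), ("exit", p.exit_time)]
        last_name, last = "start", -math.inf
        for name, t in stamps:
            if t is None:
                continue
            if t < last - 1e-9:
                v.append(f"patient {p.pid}: {name}={t} precedes {last_name}={last}")
            last_name, last = name, t
        if p.exit_time is None:
            n_censored += 1
            continue
        if p.disposition not in n_done:
            v.append(f"patient {p.pid}: exited without a terminal disposition")
            continue
        n_done[p.disposition] += 1
        if p.disposition == LWBS:
            if p.bed_time is not None:
                v.append(f"patient {p.pid}: LWBS but was bedded")
            if p.exit_time - p.door < p.tolerance - 1e-6:
                v.append(f"patient {p.pid}: LWBS before tolerance elapsed")
        else:
            if p.bed_time is None:
                v.append(f"patient {p.pid}: {p.disposition} without a bed")

    total = sum(n_done.values()) + n_censored
    if total != len(log.patients):
        v.append(f"conservation broken: {total} != {len(log.patients)} arrivals")

    # Capacity checks replayed from the exact occupancy segments.
    n = int(round(log.horizon_min / resolution))

    def _acc(arr, start, end, w=1.0):
        i0 = max(int(np.ceil(start / resolution)), 0)
        i1 = min(int(np.ceil(end / resolution)), n)
        if i1 > i0:
            arr[i0:i1] += w

    mta_occ, ft_occ, nurse_load = np.zeros(n), np.zeros(n), np.zeros(n)
    for kind, area, start, end, demand in log.bed_segments:
        if end < start - 1e-9:
            v.append(f"bed segment ends before it starts: {(kind, area, start, end)}")
        _acc(ft_occ if area == "FT" else mta_occ, start, end)
        _acc(nurse_load, start, end, demand)
    if mta_occ.max(initial=0.0) > cfg.mta_beds + 1e-9:
        v.append("MTA occupancy (incl. boarding) exceeds MTA bed count")
    if ft_occ.max(initial=0.0) > cfg.ft_beds + 1e-9:
        v.append("FT occupancy exceeds FT bed count")
    hours = ((resolution * np.arange(n)) // 60 % 24).astype(int)
    nurse_cap = cfg.schedule_for("nurse")[hours]
    if np.any(nurse_load > nurse_cap + 1e-6):
        v.append("nurse load exceeds nursing capacity")

    # Located patients can never exceed the independent in-system count.
    insys = np.zeros(n)
    for p in log.patients:
        exit_t = p.exit_time if p.exit_time is not None else log.horizon_min
        _acc(insys, p.door, exit_t)
    if np.any(mta_occ + ft_occ > insys + 1e-9):
        v.append("bedded patients exceed the independent in-system count")

    # Cross-check the census module's location sum against the replay.
    df = census(log, resolution=resolution, cfg=cfg, include_warmup=True)
    located = (df["mta_bed"] + df["ft_bed"] + df["boarding"]).to_numpy()
    if np.abs(located - (mta_occ + ft_occ)).max() > 1e-9:
        v.append("census location counts disagree with segment replay")
    if df["waiting"].min() < -1e-9:
        v.append("negative waiting-room census")

    return v


# ---------------------------------------------------------------------------
# Degenerate fixtures
# ---------------------------------------------------------------------------

def _base_fixture(**over) -> dict:
    """A minimal single-acuity ED used to build degenerate test configs."""
    d = dict(
        name="fixture",
        mta_beds=1, trauma_beds=0, ft_beds=0,
        physicians=100, pas=0, nurses=100,
        physician_schedule=None, pa_schedule=None, nurse_schedule=None,
        nurse_ratio={a: 4.0 for a in ACUITIES},
        daily_mean_arrivals=720.0,
        acuity_fractions={1: 0.0, 2: 0.0, 3: 1.0, 4: 0.0, 5: 0.0},
        hourly_shape=[1.0] * 24,
        esi2_bypass_fraction=0.0,
        boarding_nurse_factor=1.0,
        triage_duration=DurationSpec(0.0, 0.0),
        nurse_assessment=DurationSpec(0.0, 0.0),
        physician_assessment=DurationSpec(1.0, 1.0),  # shape-1 Gamma = Exp(1)
        review_assessment=DurationSpec(0.0, 0.0),
        lab_tat=DurationSpec(0.0, 0.0),
        imaging_tat=DurationSpec(0.0, 0.0),
        discharge_instruction_delay=DurationSpec(0.0, 0.0),
        boarding_delay=DurationSpec(0.0, 0.0),
        lwbs_tolerance={a: DurationSpec(math.inf, 0.0) for a in ACUITIES},
        travel_time_mean={"physician": 0.0, "pa": 0.0, "nurse": 0.0},
        complexity=ComplexityModel(
            overall_admit_rate=0.0,
            per_acuity={a: AcuityComplexity(0.0, 0.0, 0.0, 0, 0.0) for a in ACUITIES},
        ),
    )
    d.update(over)
    return d


def degenerate_fixture(name: str):
    """Tiny hand-checkable configurations with their expected behaviour.

    ``mm1``
        Single bed, stationary Poisson arrivals at 0.5/min, Exp(1 min)
        service, infinite tolerance and staff: the bed queue is M/M/1 and
        the mean door-to-bed wait equals rho/(mu - lam) = 1.0 min.
    ``mmc3``
        Three beds, 1.5/min arrivals: the M/M/3 analogue (Erlang C).
    ``zero_variance``
        All durations degenerate: each door-to-event time is exactly the
        sum of the configured means (triage 10 + nurse 5 + assessment 10,
        discharge delay 10).
    ``infinite_tolerance``
        A deliberately congested single-bed ED in which nobody ever
        reneges: the LWBS rate is exactly zero.
    ``zero_arrival``
        No arrivals: the event log is empty.
    """
    if name == "mm1":
        cfg = EDConfig(**_base_fixture())
        return cfg, {"lam": 0.5, "mu": 1.0, "c": 1, "mean_wait": mm_c_wait(0.5, 1.0, 1)}
    if name == "mmc3":
        cfg = EDConfig(**_base_fixture(mta_beds=3, daily_mean_arrivals=2160.0))
        return cfg, {"lam": 1.5, "mu": 1.0, "c": 3, "mean_wait": mm_c_wait(1.5, 1.0, 3)}
    if name == "zero_variance":
        cfg = EDConfig(**_base_fixture(
            daily_mean_arrivals=24.0,
            triage_duration=DurationSpec(10.0, 0.0),
            nurse_assessment=DurationSpec(5.0, 0.0),
            physician_assessment=DurationSpec(10.0, 0.0),
            discharge_instruction_delay=DurationSpec(10.0, 0.0),
        ))
        return cfg, {"door_to_doctor": 15.0, "door_to_disposition": 25.0,
                     "door_to_exit": 35.0}
    if name == "infinite_tolerance":
        cfg = EDConfig(**_base_fixture(
            daily_mean_arrivals=120.0,
            physician_assessment=DurationSpec(30.0, 225.0),
        ))
        return cfg, {"lwbs_rate": 0.0}
    if name == "zero_arrival":
        cfg = EDConfig(**_base_fixture(daily_mean_arrivals=0.0))
        return cfg, {"n_arrivals": 0}
    raise KeyError(f"unknown fixture {name!r}")
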