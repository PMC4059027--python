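"""Throughput metrics and explication outputs from replication event logs.

Produces the validation statistics (LWBS rate; door-to-doctor,
door-to-disposition, and door-to-exit means; patients per physician per
staffed hour; annualized patients per bed), acuity- and
disposition-stratified door-to-event tables, and minute-by-minute census and
idle-resource series.

Conventions: patients arriving inside the summary window (after warm-up)
define the arrival count; patients still in the system at the horizon are
censored — included in arrival counts and the census, excluded from all
door-to-event time means.  The LWBS-rate denominator is all arrivals.  The
patients-per-bed-year numerator is annualized arrival volume (every patient
who presented, including LWBS), which is how the per-bed utilization
benchmark is conventionally quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import ADMIT, DISCHARGE, LWBS, EventLog

__all__ = [
    "ReplicationSummary",
    "summarize",
    "aggregate_replications",
    "door_to_event_by_acuity",
    "census",
]

ACUITIES = (1, 2, 3, 4, 5)


@dataclass
class ReplicationSummary:
    """Validation metrics for one replication (times in hours)."""

    n_arrivals: int
    n_admits: int
    n_discharges: int
    n_lwbs: int
    n_censored: int
    lwbs_rate: float  # percent of all arrivals
    door_to_doctor: float
    door_to_disposition: float
    door_to_exit: float
    patients_per_doctor_hour: float
    patients_per_bed_year: float
    by_acuity: pd.DataFrame = field(repr=False, default=None)
    by_disposition: pd.DataFrame = field(repr=False, default=None)

    SCALARS = (
        "n_arrivals", "n_admits", "n_discharges", "n_lwbs", "n_censored",
        "lwbs_rate", "door_to_doctor", "door_to_disposition", "door_to_exit",
        "patients_per_doctor_hour", "patients_per_bed_year",
    )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.SCALARS}


def _window_patients(log: EventLog):
    lo, hi = log.warmup_min, log.warmup_min + log.days * 1440.0
    return [p for p in log.patients if lo <= p.door < hi]


def _mean_hours(pairs) -> float:
    vals = [b - a for a, b in pairs]
    return float(np.mean(vals)) / 60.0 if vals else 0.0


def summarize(log: EventLog, cfg=None, days: float | None = None) -> ReplicationSummary:
    """Compute the validation metrics for one replication log."""
    cfg = cfg or log.cfg
    days = days if days is not None else log.days
    pats = _window_patients(log)
    done = [p for p in pats if p.exit_time is not None]  # non-censored

    n_arr = len(pats)
    n_adm = sum(1 for p in done if p.disposition == ADMIT)
    n_dis = sum(1 for p in done if p.disposition == DISCHARGE)
    n_lwbs = sum(1 for p in done if p.disposition == LWBS)
    n_cen = n_arr - len(done)

    if n_arr == 0:
        return ReplicationSummary(0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                  by_acuity=door_to_event_by_acuity(log),
                                  by_disposition=pd.DataFrame())

    d2doc = _mean_hours((p.door, p.first_provider) for p in done
                        if p.first_provider is not None)
    d2disp = _mean_hours((p.door, p.dispo_time) for p in done
                         if p.dispo_time is not None and p.disposition != LWBS)
    d2exit = _mean_hours((p.door, p.exit_time) for p in done
                         if p.disposition != LWBS)

    seen_by_md = sum(1 for p in pats if p.provider_class == "physician")
    md_hours = cfg.staffed_hours_per_day("physician") * days
    pdh = seen_by_md / md_hours if md_hours > 0 else 0.0
    pby = (n_arr / days) * 365.0 / cfg.total_beds if cfg.total_beds else 0.0

    rows = []
    for dispo in (DISCHARGE, ADMIT):
        grp = [p for p in done if p.disposition == dispo]
        rows.append({
            "disposition": dispo,
            "n": len(grp),
            "door_to_doctor": _mean_hours((p.door, p.first_provider) for p in grp
                                          if p.first_provider is not None),
            "door_to_disposition": _mean_hours((p.door, p.dispo_time) for p in grp),
            "door_to_exit": _mean_hours((p.door, p.exit_time) for p in grp),
        })
    by_dispo = pd.DataFrame(rows).set_index("disposition")

    return ReplicationSummary(
        n_arrivals=n_arr, n_admits=n_adm, n_discharges=n_dis, n_lwbs=n_lwbs,
        n_censored=n_cen,
        lwbs_rate=100.0 * n_lwbs / n_arr,
        door_to_doctor=d2doc,
        door_to_disposition=d2disp,
        door_to_exit=d2exit,
        patients_per_doctor_hour=pdh,
        patients_per_bed_year=pby,
        by_acuity=door_to_event_by_acuity(log),
        by_disposition=by_dispo,
    )


def aggregate_replications(summaries: list) -> pd.DataFrame:
    """Mean and sample SD of each scalar metric across replications.

    Each replication is one simulated month; the SDs therefore reflect
    variation in the monthly average statistics.
    """
    if not summaries:
        raise ValueError("need at least one replication summary")
    df = pd.DataFrame([s.to_dict() for s in summaries])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1) if len(df) > 1
                         else pd.Series(0.0, index=df.columns)})


def door_to_event_by_acuity(log: EventLog) -> pd.DataFrame:
    """Per-acuity mean door-to-bed/doctor/disposition/exit (hours) + counts."""
    pats = [p for p in _window_patients(log) if p.exit_time is not None]
    rows = []
    for esi in ACUITIES:
        grp = [p for p in pats if p.esi == esi and p.disposition != LWBS]
        rows.append({
            "esi": esi,
            "n": len(grp),
            "door_to_bed": _mean_hours((p.door, p.bed_time) for p in grp
                                       if p.bed_time is not None),
            "door_to_doctor": _mean_hours((p.door, p.first_provider) for p in grp
                                          if p.first_provider is not None),
            "door_to_disposition": _mean_hours((p.door, p.dispo_time) for p in grp
                                               if p.dispo_time is not None),
            "door_to_exit": _mean_hours((p.door, p.exit_time) for p in grp),
        })
    return pd.DataFrame(rows).set_index("esi")


# ---------------------------------------------------------------------------
# Census series
# ---------------------------------------------------------------------------

def _accumulate(counts: np.ndarray, start: float, end: float,
                lo: float, resolution: float, weight: float = 1.0) -> None:
    """Add `weight` to every sample bin whose time lies in [start, end)."""
    n = counts.size
    i0 = int(np.ceil((start - lo) / resolution))
    i1 = int(np.ceil((end - lo) / resolution))
    i0, i1 = max(i0, 0), min(i1, n)
    if i1 > i0:
        counts[i0:i1] += weight


def census(log: EventLog, resolution: float = 1.0, cfg=None,
           include_warmup: bool = False) -> pd.DataFrame:
    """Step-function counts of patient locations and idle resources.

    Sampled every ``resolution`` minutes over the summary window (or the
    full horizon with ``include_warmup``).  Patient locations: waiting room,
    MTA bed, FT bed, boarding.  Idle resources: physicians, PAs, free beds,
    free nurse capacity.
    """
    cfg = cfg or log.cfg
    lo = 0.0 if include_warmup else log.warmup_min
    hi = log.horizon_min
    n = int(round((hi - lo) / resolution))
    t = lo + resolution * np.arange(n)

    cols = {
        name: np.zeros(n)
        for name in ("insys", "mta_bed", "ft_bed", "boarding", "nurse_load")
    }
    for p in log.patients:
        exit_t = p.exit_time if p.exit_time is not None else hi
        _accumulate(cols["insys"], p.door, exit_t, lo, resolution)
    # exact bed occupancy from the logged segments (handles preemption gaps)
    for kind, area, start, end, demand in log.bed_segments:
        if kind == "board":
            _accumulate(cols["boarding"], start, end, lo, resolution)
        else:
            _accumulate(cols["ft_bed" if area == "FT" else "mta_bed"],
                        start, end, lo, resolution)
        _accumulate(cols["nurse_load"], start, end, lo, resolution, weight=demand)
    located = cols["mta_bed"] + cols["ft_bed"] + cols["boarding"]
    cols["waiting"] = cols["insys"] - located

    busy = {c: np.zeros(n) for c in ("physician", "pa")}
    for c in ("physician", "pa"):
        for s, e in log.provider_busy[c]:
            _accumulate(busy[c], s, e, lo, resolution)

    hours = ((t // 60) % 24).astype(int)
    md_cap = cfg.schedule_for("physician")[hours]
    pa_cap = cfg.schedule_for("pa")[hours]
    nurse_cap = cfg.schedule_for("nurse")[hours].astype(float)

    occupied = located
    df = pd.DataFrame({
        "minute": t,
        "waiting": cols["waiting"],
        "mta_bed": cols["mta_bed"],
        "ft_bed": cols["ft_bed"],
        "boarding": cols["boarding"],
        "idle_physicians": np.maximum(md_cap - busy["physician"], 0.0),
        "idle_pas": np.maximum(pa_cap - busy["pa"], 0.0),
        "free_beds": cfg.total_beds - occupied,
        "free_nurse_capacity": nurse_cap - cols["nurse_load"],
    }).set_index("minute")
    return df
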