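"""Discrete-event kernel: event calendar, clock, and resource accounting.

The calendar pops events in ``(time, kind-priority, insertion-seq)``
lexicographic order.  The fixed kind-priority ordering resolves same-instant
races deterministically: staffing changes and resource-freeing events are
processed before bed-assignment scans, and reneging (LWBS) deadlines are
processed last — so a patient offered a bed at exactly their waiting
tolerance stays.

Resource state covers three bed pools (plain MTA, the trauma/resuscitation
subset of the MTA, and the Fast Track), pooled providers per class, and a
fractional nurse-occupancy model: each bedded patient holds an
acuity-dependent fraction of one nurse for their whole bed stay, and a bed
cannot be filled without sufficient free nursing capacity — a nursing
shortage therefore manifests as a lack of usable beds.
"""

from __future__ import annotations

import enum
import heapq
import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EventKind",
    "KIND_PRIORITY",
    "Event",
    "EventCalendar",
    "CalendarEmpty",
    "Bed",
    "ProviderPool",
    "ResourceState",
]

_EPS = 1e-9


class EventKind(enum.IntEnum):
    STAFF_CHANGE = 0
    PROVIDER_FREED = 1
    DISCHARGE_DONE = 2
    BOARDING_DONE = 3
    PREEMPT = 4
    ARRIVAL = 5
    TRIAGE_DONE = 6
    BED_ASSIGNED = 7
    NURSE_ASSESS_DONE = 8
    PHYS_ASSESS_DONE = 9
    RESULTS_READY = 10
    DISPOSITION = 11
    LWBS_DEADLINE = 12


#: Pop priority at equal times.  Resource-freeing events come first, then
#: arrival/progress events and assignment scans, and reneging deadlines last
#: (ties decided in the patient's favor).
KIND_PRIORITY = {
    EventKind.STAFF_CHANGE: 0,
    EventKind.PROVIDER_FREED: 1,
    EventKind.DISCHARGE_DONE: 1,
    EventKind.BOARDING_DONE: 1,
    EventKind.PHYS_ASSESS_DONE: 1,
    EventKind.PREEMPT: 2,
    EventKind.ARRIVAL: 3,
    EventKind.TRIAGE_DONE: 3,
    EventKind.BED_ASSIGNED: 3,
    EventKind.NURSE_ASSESS_DONE: 3,
    EventKind.RESULTS_READY: 3,
    EventKind.DISPOSITION: 3,
    EventKind.LWBS_DEADLINE: 9,
}


@dataclass(frozen=True)
class Event:
    """One pending simulation event (time in minutes since start)."""

    time: float
    kind: EventKind
    payload: tuple = ()


class CalendarEmpty(Exception):
    """Signals replication end: no pending events remain."""


class EventCalendar:
    """Time-ordered pending-event structure driving the simulation clock."""

    def __init__(self):
        self._heap: list = []
        self._seq = itertools.count()
        self.clock = 0.0

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, ev: Event) -> None:
        """Insert a future (or present-instant) event.

        Scheduling into the past is a programming error, not a data error.
        """
        if ev.time < self.clock - _EPS:
            raise RuntimeError(
                f"event {ev.kind.name} scheduled at {ev.time} before clock {self.clock}"
            )
        heapq.heappush(
            self._heap, (ev.time, KIND_PRIORITY[ev.kind], next(self._seq), ev)
        )

    def schedule_at(self, time: float, kind: EventKind, *payload) -> None:
        self.schedule(Event(time, kind, payload))

    def advance(self) -> Event:
        """Pop the minimal event per the ordering contract; advance clock."""
        if not self._heap:
            raise CalendarEmpty
        time, _prio, _seq, ev = heapq.heappop(self._heap)
        self.clock = time
        return ev

    def peek_time(self) -> float:
        if not self._heap:
            raise CalendarEmpty
        return self._heap[0][0]


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------

FREE, OCCUPIED, BOARDING_BLOCKED = "FREE", "OCCUPIED", "BOARDING_BLOCKED"
AREAS = ("MTA", "TRAUMA", "FT")


@dataclass
class Bed:
    bed_id: int
    area: str  # MTA (plain), TRAUMA (reservable MTA subset), or FT
    status: str = FREE
    patient: object = None


class ProviderPool:
    """A pooled provider class (physicians or PAs) with an hourly schedule.

    Providers are not assigned to specific patients: any idle provider can
    serve the next request.  ``busy`` counts providers in transit or at the
    bedside.  When the schedule steps down below the busy count, capacity
    recovers as providers free up (no preemption of ongoing assessments).
    """

    def __init__(self, name: str, schedule: np.ndarray):
        self.name = name
        self.schedule = np.asarray(schedule, dtype=int)
        self.busy = 0

    def capacity(self, t_min: float) -> int:
        return int(self.schedule[int(t_min // 60) % 24])

    def idle(self, t_min: float) -> int:
        return max(self.capacity(t_min) - self.busy, 0)

    def seize(self, t_min: float) -> bool:
        if self.idle(t_min) > 0:
            self.busy += 1
            return True
        return False

    def release(self) -> None:
        if self.busy <= 0:
            raise RuntimeError(f"release of idle provider pool {self.name}")
        self.busy -= 1


class ResourceState:
    """Instantaneous bed, provider, and nurse occupancy for one ED."""

    def __init__(self, cfg):
        self.beds: list[Bed] = []
        bid = 0
        for _ in range(cfg.mta_beds - cfg.trauma_beds):
            self.beds.append(Bed(bid, "MTA"))
            bid += 1
        for _ in range(cfg.trauma_beds):
            self.beds.append(Bed(bid, "TRAUMA"))
            bid += 1
        for _ in range(cfg.ft_beds):
            self.beds.append(Bed(bid, "FT"))
            bid += 1
        self.physicians = ProviderPool("physician", cfg.schedule_for("physician"))
        self.pas = ProviderPool("pa", cfg.schedule_for("pa"))
        self.nurse_schedule = cfg.schedule_for("nurse")
        self.nurse_load = 0.0

    # -- nurses -------------------------------------------------------------
    def nurse_capacity(self, t_min: float) -> float:
        return float(self.nurse_schedule[int(t_min // 60) % 24])

    def nurse_fits(self, demand: float, t_min: float) -> bool:
        return self.nurse_load + demand <= self.nurse_capacity(t_min) + _EPS

    # -- beds ---------------------------------------------------------------
    def free_beds(self, area: str) -> list[Bed]:
        if area not in AREAS:
            raise ValueError(f"unknown treatment area {area!r}")
        return [b for b in self.beds if b.area == area and b.status == FREE]

    def acquire_bed(self, area: str, nurse_demand: float, t_min: float):
        """Seize a free bed in ``area``, consuming fractional nurse capacity.

        Returns the :class:`Bed` on success, ``None`` on refusal.  Refusal
        occurs iff no free bed exists in the area or placing the patient
        would exceed nursing capacity; on refusal the state is unchanged.
        """
        if nurse_demand < 0:
            raise ValueError("nurse_demand must be nonnegative")
        free = self.free_beds(area)
        if not free or not self.nurse_fits(nurse_demand, t_min):
            return None
        bed = free[0]
        bed.status = OCCUPIED
        self.nurse_load += nurse_demand
        return bed

    def release_bed(self, bed: Bed, nurse_demand: float) -> None:
        if bed.status == FREE:
            raise RuntimeError(f"release of already-free bed {bed.bed_id}")
        bed.status = FREE
        bed.patient = None
        self.nurse_load -= nurse_demand
        if self.nurse_load < -1e-6:
            raise RuntimeError("nurse load went negative")
        if self.nurse_load < 0:
            self.nurse_load = 0.0

    # -- audits -------------------------------------------------------------
    def bed_counts(self) -> dict:
        out = {a: {FREE: 0, OCCUPIED: 0, BOARDING_BLOCKED: 0} for a in AREAS}
        for b in self.beds:
            out[b.area][b.status] += 1
        return out

    def audit(self, t_min: float) -> list[str]:
        """Conservation/capacity checks; returns violation strings."""
        v = []
        counts = self.bed_counts()
        for a in AREAS:
            total = sum(counts[a].values())
            expect = len([b for b in self.beds if b.area == a])
            if total != expect:
                v.append(f"bed conservation broken in {a}: {total} != {expect}")
        cap = self.nurse_capacity(t_min)
        if self.nurse_load > cap + 1e-6:
            v.append(f"nurse load {self.nurse_load} exceeds capacity {cap}")
        if self.nurse_load < -1e-6:
            v.append("negative nurse load")
        for pool in (self.physicians, self.pas):
            if pool.busy < 0:
                v.append(f"negative busy count in {pool.name} pool")
        return v
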