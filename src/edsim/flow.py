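"""ED process logic: streaming, triage, waiting-room priority queue with
reneging, ESI-1 preemption, treatment cycles, disposition, and boarding.

The patient pathway: arrivals are streamed by Emergency Severity Index
(ESI).  ESI-1 patients go directly to a trauma/resuscitation bed in the Main
Treatment Area, preempting a lower-acuity occupant if necessary.  A
configurable fraction of ESI-2 patients bypass triage; everyone else is
triaged (a Gamma delay) and waits for a bed.  Waiting patients are selected
by acuity, then arrival time; patients whose waiting time exceeds their
drawn tolerance leave without being seen (LWBS).  Bedded patients receive a
brief nurse assessment, then queue for a pooled provider (physicians in the
MTA, physician assistants in the Fast Track).  The provider travels to the
bedside, performs an assessment, and may order labs and/or imaging; when
results return the provider is seized again for review, possibly ordering
further test cycles.  The terminal review draws a disposition: discharges
exit after a discharge-processing delay; admits board in their bed (blocking
it) for a Gamma boarding delay before leaving the ED.
"""

from __future__ import annotations

import heapq
import io
import itertools

import numpy as np

from .config import EDConfig
from .engine import (
    BOARDING_BLOCKED,
    OCCUPIED,
    CalendarEmpty,
    EventCalendar,
    EventKind,
    ResourceState,
)
from .stochastic import RandomStream, sample_duration, sample_nhpp, sample_travel

__all__ = [
    "Patient",
    "WaitingRoom",
    "EventLog",
    "Simulation",
    "run_replication",
    "eligible_areas",
    "rep_seed",
]

# Patient stages
PRE_TRIAGE = "PRE_TRIAGE"
WAITING = "WAITING"
NURSE = "NURSE"
WAIT_PROVIDER = "WAIT_PROVIDER"
IN_ASSESS = "IN_ASSESS"
WAIT_RESULTS = "WAIT_RESULTS"
DISCHARGE_WAIT = "DISCHARGE_WAIT"
BOARDING = "BOARDING"
EXITED = "EXITED"

#: Stages during which a trauma-bed occupant may be displaced by an ESI-1
#: arrival (active treatment only; dispositioned patients are never moved).
PREEMPTABLE_STAGES = frozenset({NURSE, WAIT_PROVIDER, IN_ASSESS, WAIT_RESULTS})

DISCHARGE, ADMIT, LWBS = "DISCHARGE", "ADMIT", "LWBS"


def eligible_areas(esi: int, ft_enabled: bool) -> tuple:
    """Treatment areas a patient of this acuity may be bedded in, in
    assignment-preference order.

    ESI-1 uses trauma beds only.  ESI-2/3 use the MTA (plain beds first,
    trauma beds as overflow).  ESI-4/5 prefer the Fast Track when one is
    configured, falling back to the MTA.  Patients never switch areas once
    assigned.
    """
    if esi == 1:
        return ("TRAUMA",)
    if esi in (2, 3):
        return ("MTA", "TRAUMA")
    if ft_enabled:
        return ("FT", "MTA", "TRAUMA")
    return ("MTA", "TRAUMA")


class Patient:
    """One simulated ED visit with its milestone timestamps."""

    __slots__ = (
        "pid", "esi", "door", "tolerance", "nurse_demand",
        "stage", "bed", "epoch", "wr_entry",
        "triage_done", "bed_time", "first_provider", "dispo_time", "exit_time",
        "disposition", "provider_class",
        "cycles_done", "results_token", "results_ready",
        "nurse_done_time", "assess_kind", "assess_seize", "assess_bedside", "assess_end",
        "resume", "preempted", "lwbs_cancelled", "area_name", "seg_start", "seg_kind", "active_demand",
    )

    def __init__(self, pid: int, esi: int, door: float, tolerance: float, demand: float):
        self.pid = pid
        self.esi = esi
        self.door = door
        self.tolerance = tolerance
        self.nurse_demand = demand
        self.stage = PRE_TRIAGE
        self.bed = None
        self.epoch = 0
        self.wr_entry = 0
        self.triage_done = None
        self.bed_time = None
        self.first_provider = None
        self.dispo_time = None
        self.exit_time = None
        self.disposition = None
        self.provider_class = None
        self.cycles_done = 0
        self.results_token = 0
        self.results_ready = False
        self.nurse_done_time = None
        self.assess_kind = None
        self.assess_seize = None
        self.assess_bedside = None
        self.assess_end = None
        self.resume = None
        self.preempted = False
        self.lwbs_cancelled = False
        self.area_name = None
        self.seg_start = None
        self.seg_kind = None
        self.active_demand = demand

    @property
    def area(self):
        """Assigned treatment area (trauma beds are part of the MTA).

        Persists after exit, and after a preemption-induced re-queue: a
        patient never switches between the MTA and the FT once assigned.
        """
        return self.area_name


class WaitingRoom:
    """Priority queue of waiting patients.

    Selection order is (acuity ascending, preempted-first within acuity,
    arrival time ascending): a patient displaced by an ESI-1 re-enters at
    the head of their acuity class.
    """

    def __init__(self):
        self._heap: list = []
        self._seq = itertools.count()

    def __len__(self):
        return sum(1 for e in self._heap if self._valid(e))

    def _valid(self, entry) -> bool:
        p = entry[4]
        return p.stage == WAITING and entry[5] == p.wr_entry

    def add(self, p: Patient) -> None:
        p.wr_entry += 1
        heapq.heappush(
            self._heap,
            (p.esi, 0 if p.preempted else 1, p.door, next(self._seq), p,
             p.wr_entry),
        )

    def ordered(self) -> list:
        """Valid waiting patients in selection order (non-destructive)."""
        live = [e for e in self._heap if self._valid(e)]
        self._heap = live[:]
        heapq.heapify(self._heap)
        return [e[4] for e in sorted(live)]

    def discard(self, p: Patient) -> None:
        p.wr_entry += 1  # invalidates any live entry lazily


class EventLog:
    """Replication output: per-patient milestones plus resource-use intervals."""

    def __init__(self, cfg: EDConfig, days: float, warmup_days: float, seed: int):
        self.cfg = cfg
        self.days = days
        self.warmup_days = warmup_days
        self.seed = seed
        self.horizon_min = (warmup_days + days) * 1440.0
        self.warmup_min = warmup_days * 1440.0
        self.patients: list[Patient] = []
        self.provider_busy = {"physician": [], "pa": []}
        #: exact bed-occupancy segments: (kind 'bed'|'board', 'MTA'|'FT',
        #: start, end, nurse_demand) — preemption suspensions excluded
        self.bed_segments: list[tuple] = []
        self.audit_violations: list[str] = []

    # -- serialization ------------------------------------------------------
    MILESTONES = ("door", "triage_done", "bed", "first_doctor", "disposition", "exit")

    def to_csv(self) -> str:
        """One line per milestone: patient id, esi, area, milestone, minutes."""
        buf = io.StringIO()
        buf.write("patient_id,esi,area,milestone,clock_minutes\n")
        for p in sorted(self.patients, key=lambda q: q.pid):
            area = p.area or ""
            stamps = (
                ("door", p.door),
                ("triage_done", p.triage_done),
                ("bed", p.bed_time),
                ("first_doctor", p.first_provider),
                (f"disposition:{p.disposition}" if p.disposition else "disposition", p.dispo_time),
                ("exit", p.exit_time),
            )
            if p.disposition == LWBS:
                stamps = stamps[:-1] + ((f"exit:{LWBS}", p.exit_time),)
            for name, t in stamps:
                if t is not None:
                    buf.write(f"{p.pid},{p.esi},{area},{name},{t:.6f}\n")
        return buf.getvalue()


def rep_seed(seed: int, rep: int) -> int:
    """Deterministic per-replication seed below 2^31."""
    return (int(seed) * 100003 + 7919 * int(rep)) % (2**31 - 1)


class Simulation:
    """One replication of the ED discrete-event simulation.

    Parameters
    ----------
    cfg : EDConfig
    seed : int
        Master seed; combined with ``rep`` via :func:`rep_seed`.
    days : float
        Summary horizon in days (statistics window after warm-up).
    warmup_days : float
        Initial transient excluded from all summary statistics but included
        in the simulated horizon.
    audit : bool
        Run conservation/capacity audits after every event (slower).
    """

    def __init__(self, cfg: EDConfig, seed: int, days: float = 30.0,
                 rep: int = 0, warmup_days: float = 2.0, audit: bool = False,
                 arrival_times: dict | None = None):
        self.cfg = cfg
        self.days = float(days)
        self.warmup_days = float(warmup_days)
        self.audit = audit
        s = rep_seed(seed, rep)
        self.streams = {
            label: RandomStream(s, label)
            for label in ("arrivals", "durations", "tolerances", "routing",
                          "boarding", "travel")
        }
        self.cal = EventCalendar()
        self.state = ResourceState(cfg)
        self.wr = WaitingRoom()
        self.log = EventLog(cfg, self.days, self.warmup_days, seed)
        self.end_min = self.log.horizon_min
        self._pid = itertools.count()
        self.provider_queue = {"physician": [], "pa": []}
        self._pq_seq = itertools.count()
        self.ft_enabled = cfg.ft_beds > 0
        #: optional explicit arrivals {esi: [minutes]} replacing the NHPP draw
        #: (deterministic scenarios in tests)
        self.arrival_times = arrival_times

    # ------------------------------------------------------------------
    def _draw(self, spec) -> float:
        return sample_duration(spec, self.streams["durations"])

    def _pool(self, cls: str):
        return self.state.physicians if cls == "physician" else self.state.pas

    # -- setup ----------------------------------------------------------
    def _seed_arrivals(self) -> None:
        if self.arrival_times is not None:
            for esi, times in sorted(self.arrival_times.items()):
                for t in times:
                    self.cal.schedule_at(float(t), EventKind.ARRIVAL, esi)
            return
        horizon_h = self.end_min / 60.0
        for esi in sorted(self.cfg.arrival_profile.hourly_rate):
            times = sample_nhpp(
                self.cfg.arrival_profile.rate_for(esi), horizon_h,
                self.streams["arrivals"],
            )
            for t in times:
                self.cal.schedule_at(float(t), EventKind.ARRIVAL, esi)

    def _seed_staff_changes(self) -> None:
        for t in np.arange(60.0, self.end_min, 60.0):
            self.cal.schedule_at(float(t), EventKind.STAFF_CHANGE)

    # -- main loop -------------------------------------------------------
    def run(self) -> EventLog:
        self._seed_arrivals()
        self._seed_staff_changes()
        while True:
            try:
                if self.cal.peek_time() >= self.end_min:
                    break
                ev = self.cal.advance()
            except CalendarEmpty:
                break
            self._dispatch_event(ev)
            if self.audit:
                for viol in self.state.audit(self.cal.clock):
                    self.log.audit_violations.append(
                        f"t={self.cal.clock:.3f} {ev.kind.name}: {viol}"
                    )
        self._finalize()
        return self.log

    def _dispatch_event(self, ev) -> None:
        k = ev.kind
        if k == EventKind.ARRIVAL:
            self._on_arrival(ev.time, ev.payload[0])
        elif k == EventKind.TRIAGE_DONE:
            self._on_triage_done(ev.time, *ev.payload)
        elif k == EventKind.NURSE_ASSESS_DONE:
            self._on_nurse_done(ev.time, *ev.payload)
        elif k == EventKind.PHYS_ASSESS_DONE:
            self._on_assess_done(ev.time, *ev.payload)
        elif k == EventKind.RESULTS_READY:
            self._on_results(ev.time, *ev.payload)
        elif k == EventKind.DISCHARGE_DONE:
            self._on_exit_event(ev.time, *ev.payload)
        elif k == EventKind.BOARDING_DONE:
            self._on_exit_event(ev.time, *ev.payload)
        elif k == EventKind.LWBS_DEADLINE:
            self._on_lwbs(ev.time, *ev.payload)
        elif k == EventKind.STAFF_CHANGE:
            self._on_staff_change(ev.time)

    # -- arrival & routing ------------------------------------------------
    def _on_arrival(self, t: float, esi: int) -> None:
        tol_spec = self.cfg.lwbs_tolerance[esi]
        if np.isinf(tol_spec.mean):
            tolerance = np.inf
        else:
            tolerance = sample_duration(tol_spec, self.streams["tolerances"])
        p = Patient(next(self._pid), esi, t, tolerance, self.cfg.nurse_demand(esi))
        self.log.patients.append(p)

        if np.isfinite(tolerance):
            self.cal.schedule_at(t + tolerance, EventKind.LWBS_DEADLINE, p)

        if esi == 1:
            p.triage_done = t  # classified on sight, no triage step
            if not self._place_esi1(p, t):
                p.stage = WAITING
                self.wr.add(p)
        elif esi == 2 and self.streams["routing"].rng.random() < self.cfg.esi2_bypass_fraction:
            p.triage_done = t  # triage bypass
            p.stage = WAITING
            self.wr.add(p)
            self.scan_beds(t)
        else:
            self.cal.schedule_at(t + self._draw(self.cfg.triage_duration),
                                 EventKind.TRIAGE_DONE, p)

    def _on_triage_done(self, t: float, p: Patient) -> None:
        if p.stage != PRE_TRIAGE:  # left without being seen during triage
            return
        p.triage_done = t
        p.stage = WAITING
        self.wr.add(p)
        self.scan_beds(t)

    # -- ESI-1 trauma placement and preemption ----------------------------
    def _place_esi1(self, p: Patient, t: float) -> bool:
        bed = self.state.acquire_bed("TRAUMA", p.nurse_demand, t)
        if bed is not None:
            self._place(p, bed, t)
            return True
        victim = self._preemption_victim()
        if victim is None:
            return False
        # Nursing feasibility of the swap: victim's fraction is released.
        load_after = self.state.nurse_load - victim.nurse_demand + p.nurse_demand
        if load_after > self.state.nurse_capacity(t) + 1e-9:
            return False
        self._preempt(victim, t)
        bed = self.state.acquire_bed("TRAUMA", p.nurse_demand, t)
        if bed is None:  # pragma: no cover - preempt just freed one
            raise RuntimeError("preemption failed to free a trauma bed")
        self._place(p, bed, t)
        return True

    def _preemption_victim(self):
        """Lowest-acuity, most-recently-bedded displaceable trauma occupant."""
        cands = [
            b.patient for b in self.state.beds
            if b.area == "TRAUMA" and b.status == OCCUPIED
            and b.patient is not None and b.patient.esi > 1
            and b.patient.stage in PREEMPTABLE_STAGES
        ]
        if not cands:
            return None
        return max(cands, key=lambda q: (q.esi, q.bed_time, q.pid))

    def _preempt(self, victim: Patient, t: float) -> None:
        victim.epoch += 1  # invalidates pending nurse/assessment events
        st = victim.stage
        if st == NURSE:
            victim.resume = ("nurse", max(victim.nurse_done_time - t, 0.0))
        elif st == WAIT_PROVIDER:
            victim.resume = ("provider", victim.assess_kind, None)
        elif st == IN_ASSESS:
            cls = "pa" if victim.bed.area == "FT" else "physician"
            self._pool(cls).release()
            self.log.provider_busy[cls].append((victim.assess_seize, t))
            if victim.assess_bedside > t:
                # provider was still in transit: never reached the bedside
                if victim.first_provider == victim.assess_bedside:
                    victim.first_provider = None
                remaining = victim.assess_end - victim.assess_bedside
            else:
                remaining = max(victim.assess_end - t, 0.0)
            victim.resume = ("provider", victim.assess_kind, remaining)
            self._dispatch_providers(cls, t)
        elif st == WAIT_RESULTS:
            victim.resume = ("results",)
        bed = victim.bed
        victim.bed = None
        self._close_segment(victim, t)
        self.state.release_bed(bed, victim.nurse_demand)
        victim.preempted = True
        victim.stage = WAITING
        self.wr.add(victim)

    # -- bed assignment ----------------------------------------------------
    def scan_beds(self, t: float) -> int:
        """Assign free beds to waiting patients in priority order.

        Stops at the first patient blocked purely by nursing capacity (the
        nurse pool is global, so skipping ahead would starve high-acuity
        patients).  Returns the number of placements made.
        """
        placed = 0
        for p in self.wr.ordered():
            bed = None
            areas = eligible_areas(p.esi, self.ft_enabled)
            if p.area_name == "MTA":  # re-bedding after preemption: no switch
                areas = tuple(a for a in areas if a != "FT")
            elif p.area_name == "FT":
                areas = ("FT",)
            for area in areas:
                free = self.state.free_beds(area)
                if free:
                    bed = free[0]
                    break
            if bed is None:
                continue
            if not self.state.nurse_fits(p.nurse_demand, t):
                break
            got = self.state.acquire_bed(bed.area, p.nurse_demand, t)
            self.wr.discard(p)
            self._place(p, got, t)
            placed += 1
        return placed

    def _place(self, p: Patient, bed, t: float) -> None:
        p.bed = bed
        bed.patient = p
        p.lwbs_cancelled = True
        if p.area_name is None:
            p.area_name = "FT" if bed.area == "FT" else "MTA"
        if p.bed_time is None:
            p.bed_time = t
        p.seg_start, p.seg_kind = t, "bed"
        if p.resume is not None:
            action, *rest = p.resume
            p.resume = None
            if action == "nurse":
                self._start_nurse(p, t, duration=rest[0])
            elif action == "provider":
                kind, override = rest
                self._request_provider(p, kind, t, override)
            elif action == "results":
                if p.results_ready:
                    p.results_ready = False
                    self._request_provider(p, "review", t)
                else:
                    p.stage = WAIT_RESULTS
            return
        self._start_nurse(p, t)

    def _start_nurse(self, p: Patient, t: float, duration: float | None = None) -> None:
        p.stage = NURSE
        if duration is None:
            duration = self._draw(self.cfg.nurse_assessment)
        p.nurse_done_time = t + duration
        p.epoch += 1
        self.cal.schedule_at(p.nurse_done_time, EventKind.NURSE_ASSESS_DONE, p, p.epoch)

    def _on_nurse_done(self, t: float, p: Patient, epoch: int) -> None:
        if epoch != p.epoch or p.stage != NURSE:
            return
        self._request_provider(p, "initial", t)

    # -- providers ---------------------------------------------------------
    def _request_provider(self, p: Patient, kind: str, t: float,
                          override: float | None = None) -> None:
        p.stage = WAIT_PROVIDER
        p.assess_kind = kind
        cls = "pa" if p.bed.area == "FT" else "physician"
        heapq.heappush(self.provider_queue[cls],
                       (p.esi, t, next(self._pq_seq), p, kind, override))
        self._dispatch_providers(cls, t)

    def _dispatch_providers(self, cls: str, t: float) -> None:
        pool = self._pool(cls)
        q = self.provider_queue[cls]
        while q and pool.idle(t) > 0:
            _esi, _rt, _seq, p, kind, override = heapq.heappop(q)
            if p.stage != WAIT_PROVIDER or p.bed is None or p.assess_kind != kind:
                continue
            pool.busy += 1
            travel = sample_travel(self.cfg.travel_time_mean[cls], t, cls,
                                   self.streams["travel"])
            if override is not None:
                dur = override
            elif kind == "initial":
                dur = self._draw(self.cfg.physician_assessment)
            else:
                dur = self._draw(self.cfg.review_assessment)
            p.stage = IN_ASSESS
            p.assess_kind = kind
            p.assess_seize = t
            p.assess_bedside = t + travel
            p.assess_end = t + travel + dur
            if p.first_provider is None:
                p.first_provider = p.assess_bedside
                p.provider_class = cls
            p.epoch += 1
            self.cal.schedule_at(p.assess_end, EventKind.PHYS_ASSESS_DONE,
                                 p, p.epoch, cls, t)

    def _on_assess_done(self, t: float, p: Patient, epoch: int, cls: str,
                        seize_time: float) -> None:
        if epoch != p.epoch or p.stage != IN_ASSESS:
            return
        self._pool(cls).release()
        self.log.provider_busy[cls].append((seize_time, t))
        self._dispatch_providers(cls, t)
        kind = p.assess_kind
        rng = self.streams["routing"].rng
        cx = self.cfg.complexity.per_acuity[p.esi]
        order = False
        if kind == "initial":
            order = True  # first order decision always taken
        else:
            if p.cycles_done < cx.max_cycles and rng.random() < cx.cycle_continuation:
                order = True
        if order:
            lab = rng.random() < cx.p_lab
            imaging = rng.random() < cx.p_imaging
            if lab or imaging:
                tat = 0.0
                if lab:
                    tat = max(tat, self._draw(self.cfg.lab_tat))
                if imaging:
                    tat = max(tat, self._draw(self.cfg.imaging_tat))
                p.cycles_done += 1
                p.results_token += 1
                p.stage = WAIT_RESULTS
                self.cal.schedule_at(t + tat, EventKind.RESULTS_READY,
                                     p, p.results_token)
                return
        self._disposition(p, t)

    def _on_results(self, t: float, p: Patient, token: int) -> None:
        if token != p.results_token:
            return
        if p.stage == WAIT_RESULTS and p.bed is not None:
            self._request_provider(p, "review", t)
        elif p.stage == WAITING and p.resume == ("results",):
            p.results_ready = True  # suspended by preemption; review on re-bed

    # -- disposition, discharge, boarding ----------------------------------
    def _disposition(self, p: Patient, t: float) -> None:
        rng = self.streams["routing"].rng
        admit = rng.random() < self.cfg.complexity.per_acuity[p.esi].admit_rate
        p.dispo_time = t
        if admit:
            p.disposition = ADMIT
            p.stage = BOARDING
            self._close_segment(p, t)
            if p.bed.area == "TRAUMA" and self.state.free_beds("MTA"):
                # keep resuscitation bays clear: board in a plain MTA bed
                # when one is free (not an area switch; trauma is MTA)
                old = p.bed
                self.state.release_bed(old, p.active_demand)
                new = self.state.acquire_bed("MTA", p.active_demand, t)
                p.bed = new
                new.patient = p
            # boarded patients await transfer and hold a reduced nursing share
            reduced = p.nurse_demand * self.cfg.boarding_nurse_factor
            self.state.nurse_load -= p.active_demand - reduced
            p.active_demand = reduced
            p.seg_start, p.seg_kind = t, "board"
            p.bed.status = BOARDING_BLOCKED
            self.scan_beds(t)
            delay = sample_duration(self.cfg.boarding_delay, self.streams["boarding"])
            self.cal.schedule_at(t + delay, EventKind.BOARDING_DONE, p)
        else:
            p.disposition = DISCHARGE
            p.stage = DISCHARGE_WAIT
            delay = self._draw(self.cfg.discharge_instruction_delay)
            self.cal.schedule_at(t + delay, EventKind.DISCHARGE_DONE, p)

    def _on_exit_event(self, t: float, p: Patient) -> None:
        p.exit_time = t
        p.stage = EXITED
        bed, p.bed = p.bed, None
        self._close_segment(p, t)
        self.state.release_bed(bed, p.active_demand)
        self.scan_beds(t)

    def _close_segment(self, p: Patient, t: float) -> None:
        if p.seg_start is not None:
            self.log.bed_segments.append(
                (p.seg_kind, p.area_name, p.seg_start, t, p.active_demand)
            )
            p.seg_start = None

    # -- reneging ----------------------------------------------------------
    def _on_lwbs(self, t: float, p: Patient) -> None:
        if p.lwbs_cancelled or p.bed is not None or p.stage == EXITED:
            return
        self.wr.discard(p)
        p.disposition = LWBS
        p.dispo_time = t
        p.exit_time = t
        p.stage = EXITED

    # -- staffing ----------------------------------------------------------
    def _on_staff_change(self, t: float) -> None:
        self._dispatch_providers("physician", t)
        self._dispatch_providers("pa", t)
        self.scan_beds(t)

    # -- end of horizon -----------------------------------------------------
    def _finalize(self) -> None:
        end = self.end_min
        for p in self.log.patients:
            if p.seg_start is not None:
                self._close_segment(p, end)
        # open assessments at the horizon contribute a clipped busy interval
        for p in self.log.patients:
            if p.stage == IN_ASSESS and p.bed is not None:
                cls = "pa" if p.bed.area == "FT" else "physician"
                self.log.provider_busy[cls].append((p.assess_seize, end))
        # normalize busy intervals: clip to horizon, drop empties, sort
        for cls in ("physician", "pa"):
            iv = [
                (max(s, 0.0), min(e, end))
                for (s, e) in self.log.provider_busy[cls]
                if min(e, end) > max(s, 0.0)
            ]
            iv.sort()
            self.log.provider_busy[cls] = iv


def run_replication(cfg: EDConfig, seed: int, days: float = 30.0, rep: int = 0,
                    warmup_days: float = 2.0, audit: bool = False) -> EventLog:
    """Run one independent replication and return its event log."""
    return Simulation(cfg, seed, days=days, rep=rep,
                      warmup_days=warmup_days, audit=audit).run()
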