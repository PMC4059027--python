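"""Patient-flow logic: routing, waiting-room priority, reneging boundary,
ESI-1 preemption, treatment cycles, and conservation."""

import numpy as np
import pytest

import edsim
from edsim import DurationSpec, Simulation, WaitingRoom, run_replication
from edsim.flow import ADMIT, DISCHARGE, LWBS, Patient, eligible_areas
from edsim.oracles import degenerate_fixture, replay_audit


def deterministic_cfg(**over):
    """Zero-variance single-area config for hand-checkable scenarios."""
    cfg, _ = degenerate_fixture("zero_variance")
    for k, v in over.items():
        setattr(cfg, k, v)
    cfg.__post_init__()  # re-derive the arrival profile after overrides
    return cfg


class TestRouting:
    def test_area_eligibility_rules(self):
        assert eligible_areas(1, True) == ("TRAUMA",)
        assert eligible_areas(2, True) == ("MTA", "TRAUMA")
        assert eligible_areas(3, True) == ("MTA", "TRAUMA")
        assert eligible_areas(4, True)[0] == "FT"
        assert eligible_areas(5, False) == ("MTA", "TRAUMA")

    def test_esi4_takes_the_triage_path(self):
        cfg = deterministic_cfg(acuity_fractions={1: 0, 2: 0, 3: 0, 4: 1.0, 5: 0},
                                daily_mean_arrivals=48.0)
        log = run_replication(cfg, 3, days=2, warmup_days=0)
        done = [p for p in log.patients if p.triage_done is not None]
        assert done and all(p.triage_done == p.door + 10.0 for p in done)

    def test_esi1_skips_triage_entirely(self):
        cfg = deterministic_cfg(acuity_fractions={1: 1.0, 2: 0, 3: 0, 4: 0, 5: 0},
                                trauma_beds=1, daily_mean_arrivals=24.0)
        log = run_replication(cfg, 3, days=2, warmup_days=0)
        assert all(p.triage_done == p.door for p in log.patients)

    def test_esi2_bypass_fraction_is_binomial(self):
        cfg = deterministic_cfg(acuity_fractions={1: 0, 2: 1.0, 3: 0, 4: 0, 5: 0},
                                daily_mean_arrivals=400.0, mta_beds=100,
                                esi2_bypass_fraction=0.2)
        log = run_replication(cfg, 11, days=25, warmup_days=0)
        n = len(log.patients)
        bypassed = sum(1 for p in log.patients if p.triage_done == p.door)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(bypassed / n - 0.2) < 3 * se


class TestWaitingRoom:
    def _patient(self, pid, esi, door, preempted=False):
        p = Patient(pid, esi, door, np.inf, 0.25)
        p.stage = "WAITING"
        p.preempted = preempted
        return p

    def test_acuity_beats_arrival_time(self):
        wr = WaitingRoom()
        late_sicker = self._patient(1, 2, 40.0)
        early_milder = self._patient(2, 3, 10.0)
        wr.add(early_milder)
        wr.add(late_sicker)
        assert wr.ordered()[0] is late_sicker

    def test_fifo_within_acuity(self):
        wr = WaitingRoom()
        a, b = self._patient(1, 3, 10.0), self._patient(2, 3, 5.0)
        wr.add(a)
        wr.add(b)
        assert [p.door for p in wr.ordered()] == [5.0, 10.0]

    def test_preempted_patient_rejoins_at_head_of_class(self):
        wr = WaitingRoom()
        a = self._patient(1, 3, 5.0)
        displaced = self._patient(2, 3, 50.0, preempted=True)
        wr.add(a)
        wr.add(displaced)
        assert wr.ordered()[0] is displaced

    def test_discard_removes_lazily(self):
        wr = WaitingRoom()
        a = self._patient(1, 3, 5.0)
        wr.add(a)
        wr.discard(a)
        assert wr.ordered() == [] and len(wr) == 0


class TestReneging:
    def test_bed_exactly_at_tolerance_is_not_lwbs(self):
        """Boundary rule: the tie goes to the patient."""
        cfg = deterministic_cfg(
            triage_duration=DurationSpec(0.0, 0.0),
            physician_assessment=DurationSpec(105.0, 0.0),
            nurse_assessment=DurationSpec(0.0, 0.0),
            discharge_instruction_delay=DurationSpec(0.0, 0.0),
            lwbs_tolerance={a: DurationSpec(120.0, 0.0) for a in edsim.ACUITIES},
        )
        # A occupies the single bed for [0, 105); B waits exactly 105 < 120;
        # C's bed frees at 210, within tolerance only if the boundary favored
        # them - it does not (210 > 120 + 15).
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0, 1.0, 15.0]})
        log = sim.run()
        a, b, c = sorted(log.patients, key=lambda p: p.door)
        assert a.disposition == DISCHARGE
        assert b.disposition == DISCHARGE and b.bed_time == pytest.approx(105.0)
        assert c.disposition == LWBS and c.exit_time == pytest.approx(15.0 + 120.0)

    def test_bed_at_the_deadline_instant_survives(self):
        cfg = deterministic_cfg(
            triage_duration=DurationSpec(0.0, 0.0),
            physician_assessment=DurationSpec(120.0, 0.0),
            nurse_assessment=DurationSpec(0.0, 0.0),
            discharge_instruction_delay=DurationSpec(0.0, 0.0),
            lwbs_tolerance={a: DurationSpec(120.0, 0.0) for a in edsim.ACUITIES},
        )
        # A holds the bed for [0, 120); B's deadline fires at exactly 120,
        # the same instant the bed frees: bed assignment wins.
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0, 0.0]})
        log = sim.run()
        a, b = sorted(log.patients, key=lambda p: (p.bed_time is None, p.bed_time))
        assert b.disposition == DISCHARGE
        assert b.bed_time == pytest.approx(120.0)

    def test_infinite_tolerance_drives_lwbs_to_zero(self):
        cfg, expect = degenerate_fixture("infinite_tolerance")
        log = run_replication(cfg, 5, days=10, warmup_days=0)
        assert sum(1 for p in log.patients if p.disposition == LWBS) == 0


class TestPreemption:
    def _crowded_trauma_cfg(self):
        return deterministic_cfg(
            mta_beds=2, trauma_beds=1, nurses=100,
            acuity_fractions={1: 0, 2: 0, 3: 1.0, 4: 0, 5: 0},
            triage_duration=DurationSpec(0.0, 0.0),
            nurse_assessment=DurationSpec(0.0, 0.0),
            physician_assessment=DurationSpec(100.0, 0.0),
            discharge_instruction_delay=DurationSpec(0.0, 0.0),
        )

    def test_esi1_displaces_lowest_acuity_trauma_occupant(self):
        cfg = self._crowded_trauma_cfg()
        # Two ESI-3s fill both beds (plain MTA first, then trauma);
        # the ESI-1 arrival at t=10 preempts the trauma occupant.
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0, 1.0], 1: [10.0]})
        log = sim.run()
        esi1 = next(p for p in log.patients if p.esi == 1)
        victim = next(p for p in log.patients if p.door == 1.0)
        assert esi1.bed_time == pytest.approx(10.0)
        assert victim.preempted

    def test_preempted_patient_resumes_remaining_service(self):
        """The displaced patient keeps completed work and finishes the
        interrupted assessment, not a restarted one."""
        cfg = self._crowded_trauma_cfg()
        sim = Simulation(cfg, seed=1, days=2, warmup_days=0,
                         arrival_times={3: [0.0, 1.0], 1: [10.0]})
        log = sim.run()
        esi1 = next(p for p in log.patients if p.esi == 1)
        victim = next(p for p in log.patients if p.door == 1.0)
        # ESI-1 treatment occupies the trauma bay [10, 110).  The plain MTA
        # bed frees at t=100 (first ESI-3 exits); the victim re-beds there
        # and finishes the interrupted assessment: 91 of 100 minutes remain
        # (9 were completed before the t=10 preemption).
        assert esi1.exit_time == pytest.approx(110.0)
        assert victim.bed_time == pytest.approx(1.0)  # first bed stamp kept
        assert victim.exit_time == pytest.approx(100.0 + 91.0)
        assert replay_audit(log) == []

    def test_no_esi1_preempts_esi1(self):
        cfg = self._crowded_trauma_cfg()
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={1: [0.0, 5.0]})
        log = sim.run()
        first, second = sorted(log.patients, key=lambda p: p.door)
        assert first.bed_time == pytest.approx(0.0)
        assert second.bed_time == pytest.approx(100.0)  # waits, no preemption


class TestTreatmentAndDisposition:
    def test_no_orders_means_immediate_disposition(self):
        cfg = deterministic_cfg()  # p_lab = p_imaging = 0 in the fixture
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0]})
        (p,) = sim.run().patients
        assert p.dispo_time == pytest.approx(p.first_provider + 10.0)

    def test_zero_variance_discharge_delay_is_exact(self):
        cfg = deterministic_cfg()
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0]})
        (p,) = sim.run().patients
        assert p.exit_time == pytest.approx(p.dispo_time + 10.0)

    def test_admit_fraction_matches_admit_rate(self):
        from edsim.config import AcuityComplexity, ComplexityModel

        cfg = deterministic_cfg(
            daily_mean_arrivals=720.0, mta_beds=200, nurses=500,
            complexity=ComplexityModel(
                overall_admit_rate=0.258,
                per_acuity={a: AcuityComplexity(0.0, 0.0, 0.0, 0, 0.258)
                            for a in edsim.ACUITIES}),
        )
        log = run_replication(cfg, 7, days=20, warmup_days=0)
        done = [p for p in log.patients if p.disposition in (ADMIT, DISCHARGE)]
        frac = sum(1 for p in done if p.disposition == ADMIT) / len(done)
        se = np.sqrt(0.258 * 0.742 / len(done))
        assert abs(frac - 0.258) < 3 * se

    def test_boarding_blocks_the_bed_until_exit(self):
        cfg = deterministic_cfg(boarding_delay=DurationSpec(300.0, 0.0))
        from edsim.config import AcuityComplexity, ComplexityModel

        cfg.complexity = ComplexityModel(
            overall_admit_rate=1.0,
            per_acuity={a: AcuityComplexity(0.0, 0.0, 0.0, 0, 1.0)
                        for a in edsim.ACUITIES})
        sim = Simulation(cfg, seed=1, days=1, warmup_days=0,
                         arrival_times={3: [0.0, 5.0]})
        log = sim.run()
        a, b = sorted(log.patients, key=lambda p: p.door)
        assert a.disposition == ADMIT
        assert a.exit_time == pytest.approx(a.dispo_time + 300.0)
        assert b.bed_time == pytest.approx(a.exit_time)  # bed blocked meanwhile
        kinds = {k for k, *_ in log.bed_segments}
        assert kinds == {"bed", "board"}


class TestSystemInvariants:
    @pytest.mark.parametrize("name", ["national", "academic"])
    def test_conservation_and_audit_on_profile_runs(self, name):
        log = run_replication(edsim.builtin_profile(name), 13, days=6,
                              warmup_days=1, audit=True)
        assert log.audit_violations == []
        assert replay_audit(log) == []
        done = sum(1 for p in log.patients if p.exit_time is not None)
        censored = sum(1 for p in log.patients if p.exit_time is None)
        assert done + censored == len(log.patients)

    def test_timestamp_monotonicity_for_every_patient(self, national_cfg):
        log = run_replication(national_cfg, 29, days=6, warmup_days=1)
        for p in log.patients:
            stamps = [t for t in (p.door, p.triage_done, p.bed_time,
                                  p.first_provider, p.dispo_time, p.exit_time)
                      if t is not None]
            assert stamps == sorted(stamps)

    def test_ft_disabled_means_no_ft_patients(self, national_cfg):
        log = run_replication(national_cfg, 31, days=6, warmup_days=0)
        assert all(p.area != "FT" for p in log.patients)

    def test_ft_serves_only_low_acuity(self, academic_cfg):
        log = run_replication(academic_cfg, 31, days=6, warmup_days=0)
        ft = [p for p in log.patients if p.area == "FT"]
        assert ft, "expected Fast Track utilization in the academic profile"
        assert all(p.esi in (4, 5) for p in ft)
        pa_seen = {p.provider_class for p in ft if p.provider_class}
        assert pa_seen == {"pa"}

    def test_fixed_seed_reproduces_event_log_exactly(self, national_cfg):
        a = run_replication(national_cfg, 99, days=4, warmup_days=0)
        b = run_replication(national_cfg, 99, days=4, warmup_days=0)
        assert a.to_csv() == b.to_csv()
        c = run_replication(national_cfg, 100, days=4, warmup_days=0)
        assert a.to_csv() != c.to_csv()

    def test_more_physicians_never_slow_door_to_doctor(self, national_cfg):
        from edsim import add_resources, summarize

        base = summarize(run_replication(national_cfg, 3, days=8, warmup_days=1))
        more = add_resources(national_cfg, d_physicians=1).config
        plus = summarize(run_replication(more, 3, days=8, warmup_days=1))
        assert plus.door_to_doctor <= base.door_to_doctor + 1e-9

    def test_zero_arrival_fixture_yields_empty_log(self):
        cfg, _ = degenerate_fixture("zero_arrival")
        log = run_replication(cfg, 1, days=3, warmup_days=0)
        assert log.patients == []
        summ = edsim.summarize(log)
        assert summ.n_arrivals == 0 and summ.lwbs_rate == 0.0
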