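"""Metric computation on hand-built logs and census consistency."""

import numpy as np
import pandas as pd
import pytest

from edsim import aggregate_replications, census, door_to_event_by_acuity, summarize
from edsim.flow import ADMIT, DISCHARGE, LWBS, EventLog, Patient


def _patient(pid, esi, door, *, bed=None, doctor=None, dispo=None, exit=None,
             disposition=None, area="MTA", demand=0.25):
    p = Patient(pid, esi, door, 210.0, demand)
    p.bed_time, p.first_provider, p.dispo_time, p.exit_time = bed, doctor, dispo, exit
    p.disposition = disposition
    p.area_name = area if bed is not None else None
    if doctor is not None:
        p.provider_class = "pa" if area == "FT" else "physician"
    return p


def _log(cfg, patients, days=1.0, segments=None):
    log = EventLog(cfg, days=days, warmup_days=0.0, seed=0)
    log.patients = patients
    log.bed_segments = segments or []
    for p in patients:
        if p.bed_time is not None:
            end = p.exit_time if p.exit_time is not None else log.horizon_min
            if p.disposition == ADMIT:
                log.bed_segments.append(("bed", p.area_name, p.bed_time,
                                         p.dispo_time, p.nurse_demand))
                log.bed_segments.append(("board", p.area_name, p.dispo_time,
                                         end, p.nurse_demand))
            elif not segments:
                log.bed_segments.append(("bed", p.area_name, p.bed_time, end,
                                         p.nurse_demand))
    return log


class TestSummarize:
    def test_three_patient_log_exact_means(self, national_cfg):
        """Hand-computed door-to-event means on a fixture log."""
        pats = [
            _patient(0, 3, 0.0, bed=30.0, doctor=60.0, dispo=120.0, exit=180.0,
                     disposition=DISCHARGE),
            _patient(1, 2, 10.0, bed=20.0, doctor=40.0, dispo=100.0, exit=400.0,
                     disposition=ADMIT),
            _patient(2, 5, 50.0, dispo=260.0, exit=260.0, disposition=LWBS),
        ]
        s = summarize(_log(national_cfg, pats))
        assert s.n_arrivals == 3 and s.n_lwbs == 1 and s.n_admits == 1
        assert s.lwbs_rate == pytest.approx(100.0 / 3)
        assert s.door_to_doctor == pytest.approx(((60 - 0) + (40 - 10)) / 2 / 60)
        assert s.door_to_disposition == pytest.approx(((120 - 0) + (100 - 10)) / 2 / 60)
        assert s.door_to_exit == pytest.approx(((180 - 0) + (400 - 10)) / 2 / 60)

    def test_lwbs_rate_is_share_of_all_arrivals(self, national_cfg):
        pats = [_patient(i, 4, float(i), bed=float(i) + 5, doctor=float(i) + 10,
                         dispo=float(i) + 20, exit=float(i) + 30,
                         disposition=DISCHARGE) for i in range(97)]
        pats += [_patient(100 + i, 5, 0.0, dispo=200.0, exit=200.0,
                          disposition=LWBS) for i in range(3)]
        assert summarize(_log(national_cfg, pats)).lwbs_rate == pytest.approx(3.0)

    def test_throughput_benchmarks_use_staffed_hours_and_beds(self, national_cfg):
        pats = [_patient(i, 3, float(i), bed=float(i) + 1, doctor=float(i) + 2,
                         dispo=float(i) + 3, exit=float(i) + 4,
                         disposition=DISCHARGE) for i in range(61)]
        s = summarize(_log(national_cfg, pats, days=1.0))
        # 61 physician-hours/day in the national duty schedule
        assert s.patients_per_doctor_hour == pytest.approx(1.0)
        assert s.patients_per_bed_year == pytest.approx(61 * 365 / 32)

    def test_censored_patients_excluded_from_time_means(self, national_cfg):
        pats = [
            _patient(0, 3, 0.0, bed=10.0, doctor=20.0, dispo=30.0, exit=40.0,
                     disposition=DISCHARGE),
            _patient(1, 3, 100.0, bed=110.0, doctor=130.0),  # still in system
        ]
        s = summarize(_log(national_cfg, pats))
        assert s.n_censored == 1
        assert s.door_to_doctor == pytest.approx(20.0 / 60)

    def test_empty_log_returns_zero_summary(self, national_cfg):
        s = summarize(_log(national_cfg, []))
        assert s.n_arrivals == 0 and s.lwbs_rate == 0.0

    def test_ordering_invariant_of_means(self, national_cfg):
        s = summarize(_log(national_cfg, [
            _patient(0, 3, 0.0, bed=5.0, doctor=15.0, dispo=75.0, exit=95.0,
                     disposition=DISCHARGE)]))
        assert s.door_to_doctor <= s.door_to_disposition <= s.door_to_exit


class TestAggregate:
    def test_identical_summaries_have_zero_sd(self, national_cfg):
        pats = [_patient(0, 3, 0.0, bed=5.0, doctor=10.0, dispo=20.0, exit=30.0,
                         disposition=DISCHARGE)]
        s = summarize(_log(national_cfg, pats))
        agg = aggregate_replications([s, s, s])
        assert (agg["sd"] == 0).all()

    def test_two_point_mean_and_sd_closed_form(self, national_cfg):
        def with_lwbs(pct):
            n_lwbs = int(pct)
            pats = [_patient(i, 4, 0.0, bed=1.0, doctor=2.0, dispo=3.0, exit=4.0,
                             disposition=DISCHARGE) for i in range(100 - n_lwbs)]
            pats += [_patient(200 + i, 5, 0.0, dispo=300.0, exit=300.0,
                              disposition=LWBS) for i in range(n_lwbs)]
            return summarize(_log(national_cfg, pats))

        agg = aggregate_replications([with_lwbs(2), with_lwbs(4)])
        assert agg.loc["lwbs_rate", "mean"] == pytest.approx(3.0)
        assert agg.loc["lwbs_rate", "sd"] == pytest.approx(np.sqrt(2.0))


class TestStratified:
    def test_one_patient_per_acuity_exact_rows(self, national_cfg):
        pats = [_patient(a, a, 0.0, bed=10.0 * a, doctor=10.0 * a + 5,
                         dispo=10.0 * a + 20, exit=10.0 * a + 30,
                         disposition=DISCHARGE) for a in (1, 2, 3, 4, 5)]
        tab = door_to_event_by_acuity(_log(national_cfg, pats))
        for a in (1, 2, 3, 4, 5):
            assert tab.loc[a, "n"] == 1
            assert tab.loc[a, "door_to_bed"] == pytest.approx(10.0 * a / 60)
            assert tab.loc[a, "door_to_exit"] == pytest.approx((10.0 * a + 30) / 60)

    def test_stratified_counts_sum_to_overall(self, national_cfg):
        from edsim import run_replication

        log = run_replication(national_cfg, 21, days=5, warmup_days=1)
        s = summarize(log)
        assert s.by_acuity["n"].sum() == s.n_admits + s.n_discharges


class TestCensus:
    def test_single_patient_occupancy_window(self, national_cfg):
        pats = [_patient(0, 3, 5.0, bed=60.0, doctor=70.0, dispo=100.0,
                         exit=120.0, disposition=DISCHARGE)]
        df = census(_log(national_cfg, pats), resolution=1.0, include_warmup=True)
        m = df["mta_bed"].to_numpy()
        t = df.index.to_numpy()
        assert m[(t >= 60) & (t < 120)].min() == 1
        assert m[(t < 60) | (t >= 120)].max() == 0
        w = df["waiting"].to_numpy()
        assert w[(t >= 5) & (t < 60)].min() == 1

    def test_boarding_column_tracks_admits(self, national_cfg):
        pats = [_patient(0, 2, 0.0, bed=10.0, doctor=20.0, dispo=60.0,
                         exit=200.0, disposition=ADMIT, demand=0.25)]
        df = census(_log(national_cfg, pats), resolution=1.0, include_warmup=True)
        t = df.index.to_numpy()
        assert df["boarding"].to_numpy()[(t >= 60) & (t < 200)].min() == 1
        assert df["mta_bed"].to_numpy()[(t >= 60)].max() == 0

    def test_idle_providers_reflect_busy_intervals(self, national_cfg):
        log = _log(national_cfg, [])
        log.provider_busy["physician"] = [(0.0, 120.0), (0.0, 60.0)]
        df = census(log, resolution=1.0, include_warmup=True)
        sched = national_cfg.schedule_for("physician")[0]
        assert df["idle_physicians"].iloc[0] == sched - 2
        assert df["idle_physicians"].iloc[90] == sched - 1

    def test_location_sum_matches_replay_on_simulated_run(self, national_cfg):
        from edsim import run_replication
        from edsim.oracles import replay_audit

        log = run_replication(national_cfg, 17, days=4, warmup_days=1)
        assert replay_audit(log) == []
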