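"""Event-driven ED simulator: sampling, policies and whole-run invariants."""

import math

import numpy as np
import pytest

from emsopt.config import ScenarioConfig, ServiceDist
from emsopt.errors import InvalidParameterError
from emsopt.simulate import (
    MINUTES_PER_DAY,
    Patient,
    QueueEntry,
    apply_diversion_policy,
    bed_release_quota,
    diversion_threshold,
    generate_patients,
    interarrival_minutes,
    next_patient,
    route_checkup,
    run_simulation,
    sample_interarrivals,
)

from conftest import single_class_config


class TestInterarrivals:
    def test_inverse_transform_closed_form(self):
        # theta = 0.5 at 350/day: -ln(0.5)/350 day in minutes
        expected = -math.log(0.5) / 350.0 * MINUTES_PER_DAY
        assert interarrival_minutes(0.5, 350.0) == pytest.approx(expected)
        assert expected == pytest.approx(2.852, abs=5e-4)

    def test_zero_theta_gives_zero_gap(self):
        assert interarrival_minutes(0.0, 350.0) == 0.0

    @pytest.mark.parametrize("rate,horizon", [(-1, 10), (0, 10), (350, 0)])
    def test_invalid_parameters_rejected(self, rate, horizon):
        with pytest.raises(InvalidParameterError):
            sample_interarrivals(rate, horizon, np.random.default_rng(0))

    def test_times_sorted_and_inside_horizon(self, rng):
        t = sample_interarrivals(350.0, 5, rng)
        assert np.all(np.diff(t) > 0)
        assert t[0] >= 0 and t[-1] < 5 * MINUTES_PER_DAY

    @pytest.mark.parametrize("rate", [350.0, 425.0])
    def test_daily_counts_are_poisson(self, rate):
        t = sample_interarrivals(rate, 1000, np.random.default_rng(42))
        counts = np.bincount((t // MINUTES_PER_DAY).astype(int), minlength=1000)
        assert abs(counts.mean() - rate) / rate < 0.01
        assert 0.9 < counts.var(ddof=1) / counts.mean() < 1.1


class TestGeneratePatients:
    def test_degenerate_mix_pins_triage(self, rng):
        cfg = ScenarioConfig(triage_mix=(0, 0, 0, 1, 0), horizon_days=1, warmup_days=0)
        patients = generate_patients(cfg, rng)
        assert patients and all(p.triage == 4 for p in patients)

    def test_mix_recovered_in_large_sample(self, rng):
        mix = (0.05, 0.15, 0.40, 0.30, 0.10)
        cfg = ScenarioConfig(triage_mix=mix, noise_lambda=350, horizon_days=30)
        patients = generate_patients(cfg, rng)
        assert len(patients) > 9000
        freq = np.bincount([p.triage for p in patients], minlength=6)[1:] / len(patients)
        assert np.all(np.abs(freq - np.asarray(mix)) < 0.02)

    def test_arrivals_sorted(self, rng):
        cfg = ScenarioConfig(horizon_days=2)
        patients = generate_patients(cfg, rng)
        times = [p.arrival_time for p in patients]
        assert times == sorted(times)


class TestDiversion:
    @pytest.mark.parametrize("level,threshold", [(1.0, 1.5), (2.0, 2.0), (3.0, 2.5), (2.8, 2.4)])
    def test_threshold_interpolates_between_anchors(self, level, threshold):
        assert diversion_threshold(level) == pytest.approx(threshold)

    @pytest.mark.parametrize("level", [0.5, 3.2])
    def test_out_of_range_level_rejected(self, level):
        with pytest.raises(InvalidParameterError):
            diversion_threshold(level)

    def test_policy_truth_table(self, rng):
        mk = lambda triage: Patient(id=0, triage=triage, arrival_time=0.0)
        # urgent patients are never persuaded, however crowded
        assert not apply_diversion_policy(mk(2), 3.0, 1.0, rng)
        # below every threshold: no diversion
        assert not apply_diversion_policy(mk(4), 1.2, 1.0, rng)
        # 2.5 >= interpolated threshold 2.4 at level 2.8
        assert apply_diversion_policy(mk(5), 2.5, 2.8, rng, p_divert=1.0)
        # persuasion can fail
        assert not apply_diversion_policy(mk(5), 2.5, 2.8, rng, p_divert=0.0)


class TestRouteCheckup:
    FREE = {"urine": True, "ct": True, "xray": True}

    def test_level1_enforces_fixed_sequence(self, rng):
        assert route_checkup(["xray", "urine", "ct"], 1, self.FREE, rng) == ["urine", "ct", "xray"]

    def test_level2_prefers_a_free_needed_room(self, rng):
        occupied_ct = {"urine": True, "ct": False, "xray": True}
        plan = route_checkup(["ct", "xray"], 2, occupied_ct, rng)
        assert plan[0] == "xray" and set(plan) == {"ct", "xray"}

    def test_level3_permutations_uniform(self, rng):
        counts = {}
        for _ in range(6000):
            plan = tuple(route_checkup(["urine", "ct", "xray"], 3, self.FREE, rng))
            counts[plan] = counts.get(plan, 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c / 6000 - 1 / 6) < 0.02

    def test_unknown_level_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            route_checkup(["urine"], 4, self.FREE, rng)


class TestBedReleaseQuota:
    @pytest.mark.parametrize(
        "frac,level,quota",
        [
            (0.22, 2, 10),
            (0.30, 3, 15),
            (0.16, 1, 5),
            (0.10, 1, 0),
            (0.10, 2, 0),
            (0.10, 3, 0),
            (0.15, 1, 0),  # strictly greater-than thresholds
            (0.20, 2, 0),
            (0.25, 3, 0),
        ],
    )
    def test_quota_table(self, frac, level, quota):
        assert bed_release_quota(frac, level) == quota

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            bed_release_quota(1.2, 1)
        with pytest.raises(InvalidParameterError):
            bed_release_quota(0.2, 0)


class TestNextPatient:
    def _queue(self):
        p5 = Patient(id=0, triage=5, arrival_time=0.0)
        p4 = Patient(id=1, triage=4, arrival_time=10.0)
        return [QueueEntry(p5, 0.0, 30.0, 0), QueueEntry(p4, 10.0, 12.0, 1)]

    def test_level3_triage4_first(self):
        assert next_patient(self._queue(), 3).patient.triage == 4

    def test_level2_registration_order(self):
        assert next_patient(self._queue(), 2).patient.triage == 5

    def test_level1_shortest_examination(self):
        assert next_patient(self._queue(), 1).expected_exam_min == 12.0

    def test_empty_queue_rejected(self):
        with pytest.raises(InvalidParameterError):
            next_patient([], 2)


class TestRunSimulation:
    def test_near_zero_rate_yields_empty_result(self):
        cfg = ScenarioConfig(noise_lambda=1e-3, horizon_days=1, warmup_days=0, seed=1)
        res = run_simulation(cfg)
        if res.n_arrived == 0:
            assert res.empty and math.isnan(res.mean_ST)

    def test_first_patient_hand_traced_system_time(self):
        dists = {
            "registration": ServiceDist("deterministic", {"value": 10.0}),
            "exam": ServiceDist("deterministic", {"value": 20.0}),
            "urine": ServiceDist("deterministic", {"value": 0.0}),
            "ct": ServiceDist("deterministic", {"value": 0.0}),
            "xray": ServiceDist("deterministic", {"value": 0.0}),
        }
        cfg = ScenarioConfig(
            noise_lambda=5.0,
            horizon_days=1,
            warmup_days=0,
            service_dists=dists,
            checkup_probs={"urine": 0.0, "ct": 0.0, "xray": 0.0},
            admit_probs=(0, 0, 0, 0, 0),
            p_divert=0.0,
            outpatient_rate_per_day=0.0,
            seed=3,
        )
        res = run_simulation(cfg)
        assert res.n_arrived >= 1
        first = res.patients[0]
        # empty system on arrival: no waiting, S = (10, 20)
        assert first.system_time == pytest.approx(30.0)
        assert sum(w for _, w in first.waits) == pytest.approx(0.0)

    def test_seed_determinism(self, small_scenario):
        a = run_simulation(small_scenario)
        b = run_simulation(small_scenario)
        assert a.mean_ST == b.mean_ST and a.mean_EDWINC == b.mean_EDWINC
        assert [(p.id, p.triage, p.departure_time) for p in a.patients] == [
            (p.id, p.triage, p.departure_time) for p in b.patients
        ]
        assert a.daily_edwinc == b.daily_edwinc

    def test_conservation_and_trace_consistency(self, small_scenario):
        res = run_simulation(small_scenario)
        assert res.n_diverted + res.n_admitted + res.n_discharged == res.n_arrived
        for p in res.patients:
            assert p.departure_time >= p.arrival_time
            assert all(w >= 0 for _, w in p.waits)
            assert all(s >= 0 for _, s in p.services)
            assert p.system_time == pytest.approx(
                sum(w for _, w in p.waits) + sum(s for _, s in p.services)
            )
            if p.diverted:
                # triage assessment only: no service beyond registration
                assert all(station == "registration" for station, _ in p.services)
                assert p.triage in (4, 5)
        assert all(v >= 0 for _, v in res.daily_edwinc)

    def test_more_physicians_never_slower(self):
        diffs = []
        for seed in range(6):
            cfg1 = ScenarioConfig(signal_M=1, horizon_days=3, warmup_days=1, seed=seed)
            cfg2 = cfg1.replace(signal_M=2)
            diffs.append(run_simulation(cfg2).mean_ST - run_simulation(cfg1).mean_ST)
        assert np.mean(diffs) <= 1.0  # Monte-Carlo slack, minutes


def erlang_c_mean_wait(lam: float, mu: float, c: int) -> float:
    """Closed-form M/M/c mean queue wait (independent oracle)."""
    a = lam / mu
    rho = a / c
    assert rho < 1
    terms = [a**k / math.factorial(k) for k in range(c)]
    tail = a**c / (math.factorial(c) * (1 - rho))
    p_wait = tail / (sum(terms) + tail)
    return p_wait / (c * mu - lam)


class TestQueueingOracle:
    @pytest.mark.parametrize(
        "per_day,exam_mean,c",
        [
            (288.0, 4.0, 1),  # rho = 0.8
            (432.0, 5.0, 2),  # rho = 0.75
        ],
    )
    def test_mmc_mean_wait_matches_erlang_c(self, per_day, exam_mean, c):
        cfg = single_class_config(per_day, exam_mean, c, horizon_days=60, seed=11)
        res = run_simulation(cfg)
        warm = cfg.warmup_days * MINUTES_PER_DAY
        waits = [
            w
            for p in res.patients
            if p.arrival_time >= warm
            for station, w in p.waits
            if station == "exam"
        ]
        lam = per_day / MINUTES_PER_DAY
        expected = erlang_c_mean_wait(lam, 1.0 / exam_mean, c)
        assert np.mean(waits) == pytest.approx(expected, rel=0.15)
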