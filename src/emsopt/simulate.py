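"""Discrete-event simulator of internal-medicine patient flow through an ED.

One call to :func:`run_simulation` is one replication: patients arrive as a
Poisson stream (interarrivals sampled by the inverse transform of the
exponential), are triaged on the five-level TTAS scale, queue for
registration and then for one of ``M`` physicians (strict priority for
triage 1-3; the policy among triage 4/5 is control factor D), possibly
visit the urine / CT / X-ray checkup rooms (routing policy is control
factor B, with a competing outpatient stream on the same rooms), and are
finally discharged or admitted.  Admitted patients board in the ED until
the internal-medicine department releases a bed quota (control factor C).
Control factor A diverts low-acuity arrivals to outpatient clinics when the
previous day's crowding index EDWIN^C exceeded a threshold.

The engine is a classic event-calendar loop over a heap; all stochastic
draws come from a single seeded generator, so a replication is a pure
function of its :class:`~emsopt.config.ScenarioConfig`.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .config import CHECKUP_ROOMS, ScenarioConfig
from .errors import InvalidParameterError
from .metrics import EdStateSnapshot, edwin_c

__all__ = [
    "Patient",
    "SimResult",
    "QueueEntry",
    "MINUTES_PER_DAY",
    "interarrival_minutes",
    "sample_interarrivals",
    "generate_patients",
    "diversion_threshold",
    "apply_diversion_policy",
    "route_checkup",
    "bed_release_quota",
    "next_patient",
    "run_simulation",
]

MINUTES_PER_DAY = 1440.0
CANONICAL_ROOM_ORDER = CHECKUP_ROOMS  # urine -> CT -> X-ray


@dataclass
class Patient:
    """One simulated ED visit."""

    id: int
    triage: int
    arrival_time: float
    waits: list[tuple[str, float]] = field(default_factory=list)
    services: list[tuple[str, float]] = field(default_factory=list)
    diverted: bool = False
    admitted: bool = False
    departure_time: float = math.nan

    @property
    def system_time(self) -> float:
        return sum(w for _, w in self.waits) + sum(s for _, s in self.services)

    @property
    def disposition(self) -> str:
        if self.diverted:
            return "diverted"
        return "admitted" if self.admitted else "discharged"


@dataclass
class SimResult:
    """Outcome of one replication."""

    patients: list[Patient]
    daily_edwinc: list[tuple[int, float]]
    hourly_edwinc: list[tuple[float, float]]
    mean_ST: float
    mean_EDWINC: float
    replication_seed: int
    n_arrived: int = 0
    n_diverted: int = 0
    n_admitted: int = 0
    n_discharged: int = 0

    @property
    def empty(self) -> bool:
        return math.isnan(self.mean_ST)


# ---------------------------------------------------------------------------
# Elementary sampling and policy operations


def interarrival_minutes(theta: float, rate_per_day: float) -> float:
    """Inverse-transform exponential interarrival: x = -ln(1 - theta) / lambda."""
    if rate_per_day <= 0:
        raise InvalidParameterError("rate_per_day must be > 0")
    if not 0.0 <= theta < 1.0:
        raise InvalidParameterError("theta must lie in [0, 1)")
    return -math.log(1.0 - theta) / rate_per_day * MINUTES_PER_DAY


def sample_interarrivals(
    rate_per_day: float, horizon_days: float, rng: np.random.Generator
) -> np.ndarray:
    """Arrival times (minutes) of a Poisson stream over ``horizon_days``.

    Interarrivals are generated by the inverse transform
    ``x = -ln(1 - theta) / lambda`` with ``theta ~ Uniform(0, 1)``, so the
    daily counts are Poisson(``rate_per_day``) in distribution.
    """
    if rate_per_day <= 0 or horizon_days <= 0:
        raise InvalidParameterError("rate_per_day and horizon_days must be > 0")
    end = horizon_days * MINUTES_PER_DAY
    rate_per_min = rate_per_day / MINUTES_PER_DAY
    expected = rate_per_day * horizon_days
    times: list[np.ndarray] = []
    total = 0.0
    while total < end:
        chunk = max(64, int(expected * 0.25))
        theta = rng.random(chunk)
        gaps = -np.log1p(-theta) / rate_per_min
        cum = total + np.cumsum(gaps)
        times.append(cum)
        total = float(cum[-1])
    arrivals = np.concatenate(times)
    return arrivals[arrivals < end]


def generate_patients(config: ScenarioConfig, rng: np.random.Generator) -> list[Patient]:
    """Arrivals with i.i.d. triage levels sampled from the configured mix."""
    arrivals = sample_interarrivals(config.noise_lambda, config.horizon_days, rng)
    mix = np.asarray(config.triage_mix)
    if abs(mix.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("triage_mix must sum to 1")
    triages = rng.choice(np.arange(1, 6), size=arrivals.size, p=mix / mix.sum())
    return [
        Patient(id=i, triage=int(t), arrival_time=float(a))
        for i, (a, t) in enumerate(zip(arrivals, triages))
    ]


def diversion_threshold(factor_A: float) -> float:
    """EDWIN^C trigger for persuading triage-4/5 arrivals to outpatient care.

    The three discrete policy levels anchor thresholds 1.5, 2.0 and 2.5;
    fractional levels interpolate linearly so the optimizer can treat the
    factor as continuous on [1, 3].
    """
    if not 1.0 <= factor_A <= 3.0:
        raise InvalidParameterError(f"factor_A must lie in [1, 3], got {factor_A}")
    return 1.5 + (factor_A - 1.0) * 0.5


def apply_diversion_policy(
    patient: Patient,
    prev_day_edwinc: float,
    factor_A: float,
    rng: np.random.Generator,
    p_divert: float = 1.0,
) -> bool:
    """Whether this arrival is persuaded to an outpatient clinic instead.

    Only triage 4/5 patients are ever diverted, and only when yesterday's
    crowding index reached the factor-A threshold; persuasion succeeds with
    probability ``p_divert``.
    """
    if patient.triage not in (4, 5):
        return False
    if prev_day_edwinc < diversion_threshold(factor_A):
        return False
    return bool(rng.random() < p_divert)


def route_checkup(
    needed: Sequence[str],
    factor_B: int,
    room_free: Mapping[str, bool],
    rng: np.random.Generator,
) -> list[str]:
    """Ordered plan over the checkup rooms a patient still needs.

    Level 1 enforces the fixed sequence urine -> CT -> X-ray.  Level 2 puts
    currently-free needed rooms first (canonical order within each group),
    so an occupied room is skipped and revisited later; the engine re-plans
    after every completed checkup.  Level 3 is a uniformly random
    permutation of the needed rooms.
    """
    for room in needed:
        if room not in room_free:
            raise InvalidParameterError(f"room_free does not cover {room!r}")
    ordered = [r for r in CANONICAL_ROOM_ORDER if r in needed]
    if factor_B == 1:
        return ordered
    if factor_B == 2:
        free = [r for r in ordered if room_free[r]]
        busy = [r for r in ordered if not room_free[r]]
        return free + busy
    if factor_B == 3:
        idx = rng.permutation(len(ordered))
        return [ordered[i] for i in idx]
    raise InvalidParameterError(f"factor_B must be 1, 2 or 3, got {factor_B}")


def bed_release_quota(waiting_fraction: float, factor_C: int) -> int:
    """Empty internal-medicine beds released to the ED under the factor-C policy.

    Level 1: quota 5 if more than 15% of ED patients await a sickbed;
    level 2: quota 10 above 20%; level 3: quota 15 above 25%; else 0.
    """
    if not 0.0 <= waiting_fraction <= 1.0:
        raise InvalidParameterError("waiting_fraction must lie in [0, 1]")
    table = {1: (0.15, 5), 2: (0.20, 10), 3: (0.25, 15)}
    if factor_C not in table:
        raise InvalidParameterError(f"factor_C must be 1, 2 or 3, got {factor_C}")
    threshold, quota = table[factor_C]
    return quota if waiting_fraction > threshold else 0


class QueueEntry(NamedTuple):
    """A triage-4/5 patient waiting for a physician."""

    patient: Patient
    registered_at: float
    expected_exam_min: float
    seq: int  # FIFO tie-breaker


def next_patient(queue: Sequence[QueueEntry], factor_D: int) -> QueueEntry:
    """Select the next triage-4/5 patient under the factor-D sequencing policy.

    Level 1 takes the shortest expected examination (ties by registration);
    level 2 is first-come-first-served by registration; level 3 serves all
    triage 4 before any triage 5, FIFO within each class.  Triage 1-3
    patients are dispatched by a strict-priority rule before this policy is
    consulted.
    """
    if not queue:
        raise InvalidParameterError("next_patient requires a non-empty queue")
    if factor_D == 1:
        return min(queue, key=lambda e: (e.expected_exam_min, e.registered_at, e.seq))
    if factor_D == 2:
        return min(queue, key=lambda e: (e.registered_at, e.seq))
    if factor_D == 3:
        return min(queue, key=lambda e: (e.patient.triage, e.registered_at, e.seq))
    raise InvalidParameterError(f"factor_D must be 1, 2 or 3, got {factor_D}")


# ---------------------------------------------------------------------------
# Event-driven engine

_ARRIVAL, _REG_DONE, _EXAM_DONE, _ROOM_DONE, _OP_ARRIVAL, _HOURLY, _DAY_END = range(7)


class _Engine:
    def __init__(self, config: ScenarioConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.heap: list = []
        self.seq = itertools.count()
        self.now = 0.0
        self.horizon_end = config.horizon_days * MINUTES_PER_DAY

        self.present = [0] * 5  # by triage level
        self.boarding: list[Patient] = []
        self.reg_queue: list[tuple[float, int, Patient]] = []
        self.reg_busy = 0
        self.phys_queue: list[QueueEntry] = []
        self.phys_busy = 0
        self.room_busy = {r: 0 for r in CHECKUP_ROOMS}
        self.room_caps = {r: config.exam_rooms[r] for r in CHECKUP_ROOMS}
        # room queues hold (is_op, enqueue_time, seq, payload)
        self.room_queues: dict[str, list] = {r: [] for r in CHECKUP_ROOMS}

        self.prev_day_edwinc = config.initial_prev_day_edwinc
        self.last_edwinc = 0.0
        self.hourly: list[tuple[float, float]] = []
        self.today_hours: list[float] = []
        self.daily: list[tuple[int, float]] = []
        self.patients: list[Patient] = []
        self.exam_draws: dict[int, float] = {}
        self.pending_rooms: dict[int, list[str]] = {}
        self.queue_entered: dict[int, tuple[str, float]] = {}

    # -- event plumbing -----------------------------------------------------
    def push(self, time: float, kind: int, payload=None) -> None:
        heapq.heappush(self.heap, (time, next(self.seq), kind, payload))

    def schedule_static(self) -> None:
        cfg = self.cfg
        for p in generate_patients(cfg, self.rng):
            self.patients.append(p)
            self.push(p.arrival_time, _ARRIVAL, p)
        if cfg.outpatient_rate_per_day > 0:
            for room in CHECKUP_ROOMS:
                for t in sample_interarrivals(
                    cfg.outpatient_rate_per_day, cfg.horizon_days, self.rng
                ):
                    self.push(float(t), _OP_ARRIVAL, room)
        hours = int(cfg.horizon_days * 24)
        for h in range(1, hours + 1):
            self.push(h * 60.0, _HOURLY, None)
        for d in range(1, cfg.horizon_days + 1):
            self.push(d * MINUTES_PER_DAY, _DAY_END, d - 1)

    def service_time(self, station: str) -> float:
        return self.cfg.service_dists[station].sample(self.rng)

    # -- station dispatch ---------------------------------------------------
    def try_start_registration(self) -> None:
        while self.reg_queue and self.reg_busy < self.cfg.registration_servers:
            enq, _, patient = heapq.heappop(self.reg_queue)
            self.reg_busy += 1
            wait = self.now - enq
            patient.waits.append(("registration", wait))
            dur = self.service_time("registration")
            patient.services.append(("registration", dur))
            self.push(self.now + dur, _REG_DONE, patient)

    def try_start_physician(self) -> None:
        while self.phys_queue and self.phys_busy < self.cfg.signal_M:
            urgent = [e for e in self.phys_queue if e.patient.triage <= 3]
            if urgent:
                entry = min(urgent, key=lambda e: (e.patient.triage, e.registered_at, e.seq))
            else:
                entry = next_patient(self.phys_queue, self.cfg.factor_D)
            self.phys_queue.remove(entry)
            self.phys_busy += 1
            patient = entry.patient
            patient.waits.append(("exam", self.now - entry.registered_at))
            dur = self.exam_draws.pop(patient.id)
            patient.services.append(("exam", dur))
            self.push(self.now + dur, _EXAM_DONE, patient)

    def room_is_free(self, room: str) -> bool:
        return self.room_busy[room] < self.room_caps[room]

    def try_start_room(self, room: str) -> None:
        queue = self.room_queues[room]
        fifo_key = lambda job: (job[1], job[2])  # (enqueue time, seq)
        while queue and self.room_is_free(room):
            if self.cfg.factor_B in (1, 2):
                # ED patients have priority over the outpatient stream
                ed_jobs = [job for job in queue if not job[0]]
                job = min(ed_jobs, key=fifo_key) if ed_jobs else min(queue, key=fifo_key)
            else:
                job = min(queue, key=fifo_key)
            queue.remove(job)
            self.room_busy[room] += 1
            is_op, enq, _, payload = job
            dur = self.service_time(room)
            if not is_op:
                payload.waits.append((room, self.now - enq))
                payload.services.append((room, dur))
            self.push(self.now + dur, _ROOM_DONE, (room, is_op, payload))

    def enqueue_room(self, patient: Patient) -> None:
        """Send the patient to the next checkup room under the factor-B plan."""
        pending = self.pending_rooms[patient.id]
        if not pending:
            self.dispose(patient)
            return
        if self.cfg.factor_B == 2:
            free = {r: self.room_is_free(r) for r in CHECKUP_ROOMS}
            plan = route_checkup(pending, 2, free, self.rng)
        else:
            plan = pending  # level 1 / 3 plans are fixed at exam completion
        room = plan[0]
        self.pending_rooms[patient.id] = [r for r in pending if r != room]
        self.room_queues[room].append((False, self.now, next(self.seq), patient))
        self.try_start_room(room)

    # -- dispositions -------------------------------------------------------
    def dispose(self, patient: Patient) -> None:
        self.pending_rooms.pop(patient.id, None)
        admit_p = self.cfg.admit_probs[patient.triage - 1]
        if self.rng.random() < admit_p:
            patient.admitted = True
            self.boarding.append(patient)
            # stays present (boarding) until a bed quota releases it
        else:
            self.depart(patient)

    def depart(self, patient: Patient) -> None:
        patient.departure_time = self.now
        self.present[patient.triage - 1] -= 1

    def release_beds(self) -> None:
        total_present = sum(self.present)
        if total_present <= 0:
            return
        frac = min(1.0, len(self.boarding) / total_present)
        quota = bed_release_quota(frac, self.cfg.factor_C)
        for _ in range(min(quota, len(self.boarding))):
            patient = self.boarding.pop(0)
            self.depart(patient)

    def snapshot_edwinc(self) -> float:
        ba = len(self.boarding)
        if self.cfg.beds_Bt - ba <= 0:
            return self.last_edwinc  # carry the last valid value forward
        snap = EdStateSnapshot(
            counts_n=tuple(self.present),
            physicians_Na=self.cfg.signal_M,
            beds_Bt=self.cfg.beds_Bt,
            admitted_BA=ba,
        )
        return edwin_c(snap)

    # -- handlers -----------------------------------------------------------
    def handle(self, kind: int, payload) -> None:
        if kind == _ARRIVAL:
            patient: Patient = payload
            self.present[patient.triage - 1] += 1
            heapq.heappush(self.reg_queue, (self.now, next(self.seq), patient))
            self.try_start_registration()
        elif kind == _REG_DONE:
            patient = payload
            self.reg_busy -= 1
            self.try_start_registration()
            if apply_diversion_policy(
                patient, self.prev_day_edwinc, self.cfg.factor_A, self.rng, self.cfg.p_divert
            ):
                patient.diverted = True
                self.depart(patient)
            else:
                self.exam_draws[patient.id] = self.service_time("exam")
                self.phys_queue.append(
                    QueueEntry(patient, self.now, self.exam_draws[patient.id], next(self.seq))
                )
                self.try_start_physician()
        elif kind == _EXAM_DONE:
            patient = payload
            self.phys_busy -= 1
            self.try_start_physician()
            needed = [
                r for r in CHECKUP_ROOMS
                if self.rng.random() < self.cfg.checkup_probs.get(r, 0.0)
            ]
            if not needed:
                self.dispose(patient)
            else:
                free = {r: self.room_is_free(r) for r in CHECKUP_ROOMS}
                self.pending_rooms[patient.id] = route_checkup(
                    needed, self.cfg.factor_B, free, self.rng
                )
                self.enqueue_room(patient)
        elif kind == _ROOM_DONE:
            room, is_op, obj = payload
            self.room_busy[room] -= 1
            self.try_start_room(room)
            if not is_op:
                if self.pending_rooms.get(obj.id):
                    self.enqueue_room(obj)
                else:
                    self.dispose(obj)
        elif kind == _OP_ARRIVAL:
            room = payload
            self.room_queues[room].append((True, self.now, next(self.seq), None))
            self.try_start_room(room)
        elif kind == _HOURLY:
            value = self.snapshot_edwinc()
            self.last_edwinc = value
            self.hourly.append((self.now, value))
            self.today_hours.append(value)
            self.release_beds()
        elif kind == _DAY_END:
            day = payload
            if self.today_hours:
                agg = {
                    "mean": lambda v: float(np.mean(v)),
                    "max": lambda v: float(np.max(v)),
                    "last": lambda v: float(v[-1]),
                }[self.cfg.prev_day_aggregation](self.today_hours)
            else:
                agg = 0.0
            self.prev_day_edwinc = agg
            self.daily.append((day, agg))
            self.today_hours = []

    def run(self) -> SimResult:
        self.schedule_static()
        while self.heap:
            self.now, _, kind, payload = heapq.heappop(self.heap)
            self.handle(kind, payload)
        # flush: boarders still waiting at the end keep their admitted
        # disposition; their ED stay is censored at the last event time
        for patient in self.boarding:
            self.depart(patient)
        self.boarding = []

        cfg = self.cfg
        warm = cfg.warmup_days * MINUTES_PER_DAY
        st_values = [
            p.system_time
            for p in self.patients
            if not p.diverted and p.arrival_time >= warm and not math.isnan(p.departure_time)
        ]
        daily_post = [v for d, v in self.daily if d >= cfg.warmup_days]
        mean_st = float(np.mean(st_values)) if st_values else math.nan
        mean_ew = float(np.mean(daily_post)) if daily_post else math.nan
        return SimResult(
            patients=self.patients,
            daily_edwinc=self.daily,
            hourly_edwinc=self.hourly,
            mean_ST=mean_st,
            mean_EDWINC=mean_ew,
            replication_seed=cfg.seed,
            n_arrived=len(self.patients),
            n_diverted=sum(p.diverted for p in self.patients),
            n_admitted=sum(p.admitted for p in self.patients),
            n_discharged=sum(
                (not p.diverted and not p.admitted) for p in self.patients
            ),
        )


def run_simulation(config: ScenarioConfig) -> SimResult:
    """Run one seeded replication of the ED model; deterministic given the config."""
    return _Engine(config).run()
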