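"""Discrete event simulation of the referral pathways.

Each referral is an agent that enters the model at its referral instant and
moves through its sampled pathway's stages.  A stage is an inter-stage wait
(booking/backlog delay, sampled from the configured distribution) followed
by a staffed activity that must acquire a server of the required role.
Staff work weekdays 08:30–18:30, with a reduced weekend shift (a configured
fraction of the weekday headcount, floored; GPs never work weekends).
Queueing is first-come first-served within a priority class.  Agents exit
when their diagnosis is communicated; communication itself (letter, email,
telephone or face-to-face slot) consumes no staffed capacity but adds a
method-specific delay.

Three waiting-time endpoints are recorded per patient, all in days from
that patient's own referral: time to clinical diagnosis (the consultant's
triage decision), time to histopathological diagnosis (biopsy-reliant
pathways only) and time to diagnosis communication (pathway exit).

Arrivals stop at the end of the 1-year horizon but the simulation runs to
drain, so every arriving agent contributes one complete record — there are
no no-shows, dropouts or deaths in the model.  The engine is a plain
event-queue simulator (heap-ordered events, calendar-constrained resource
pools); identical seeds give identical event logs.
"""

from __future__ import annotations

import heapq
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import (
    ArmConfig,
    ArmDistribution,
    ArrivalProcess,
    DelaySpec,
    ENDPOINTS,
    Stage,
)

DAY_MINUTES = 24.0 * 60.0
#: Daily staffed service window, as fractions of a day (08:30–18:30).
WINDOW_OPEN = 8.5 / 24.0
WINDOW_CLOSE = 18.5 / 24.0
HORIZON_DAYS = 365.0


# ---------------------------------------------------------------------------
# Capacity calendar


@dataclass(frozen=True)
class CapacityCalendar:
    """Per-role concurrent server counts by day type, plus the service window.

    Day 0 of simulation time is a Monday; days 5 and 6 of each week are the
    weekend.  Weekend capacity is ``floor(weekend_fraction × weekday
    count)``, and zero for roles not available at weekends.
    """

    weekday_counts: dict[str, int]
    weekend_counts: dict[str, int]
    window: tuple[float, float] = (WINDOW_OPEN, WINDOW_CLOSE)

    @staticmethod
    def is_weekend(t: float) -> bool:
        return int(t) % 7 >= 5

    def capacity(self, role: str, t: float) -> int:
        counts = self.weekend_counts if self.is_weekend(t) else self.weekday_counts
        return counts.get(role, 0)

    def next_feasible_start(self, role: str, t: float, service_days: float) -> float:
        """Earliest time >= t at which a service can both start and finish
        inside one staffed window of a day with non-zero capacity."""
        open_, close = self.window
        if service_days > close - open_:
            raise ValueError("service longer than the daily staffed window")
        t_cur = t
        for _ in range(4000):  # bounded scan; ~11 years of calendar
            day = math.floor(t_cur)
            if self.capacity(role, day) > 0:
                start = max(t_cur, day + open_)
                if start + service_days <= day + close:
                    return start
            t_cur = day + 1.0
        raise RuntimeError(f"no feasible service window found for role {role!r}")


def build_capacity_calendar(
    staff_counts: dict[str, int],
    weekend_fraction: float = 0.7,
    weekend_unavailable: set[str] = frozenset({"GP"}),
) -> CapacityCalendar:
    """Build the staffing calendar from headcounts and a weekend fraction.

    Weekend capacity is floored (one consultant at a 0.7 weekend fraction
    gives a weekend capacity of zero).
    """
    if not 0.0 <= weekend_fraction <= 1.0:
        raise ValueError("weekend_fraction must be in [0, 1]")
    for role, n in staff_counts.items():
        if n < 0:
            raise ValueError(f"negative staff count for {role}")
    weekend = {
        role: 0 if role in weekend_unavailable else math.floor(weekend_fraction * n)
        for role, n in staff_counts.items()
    }
    return CapacityCalendar(dict(staff_counts), weekend)


# ---------------------------------------------------------------------------
# Arrivals


def generate_arrivals(
    process: ArrivalProcess,
    rng: np.random.Generator,
    horizon: float = HORIZON_DAYS,
) -> np.ndarray:
    """Sample a seasonal Poisson referral stream over ``[0, horizon)`` days.

    The year is divided into 12 equal-length months; month ``m`` receives a
    Poisson count with mean ``annual_volume × w_m / 12`` (weights
    normalised to sum to 12), with arrival instants uniform within the
    month.  The expected total equals ``annual_volume`` exactly.
    """
    weights = process.normalized_weights()
    month_len = horizon / 12.0
    times = []
    for m, w in enumerate(weights):
        n = rng.poisson(process.annual_volume * w / 12.0)
        if n:
            times.append(m * month_len + rng.uniform(0.0, month_len, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


# ---------------------------------------------------------------------------
# Delay sampling


def sample_delay(spec: DelaySpec, rng: np.random.Generator, mean_override: float | None = None) -> float:
    """Draw one inter-stage wait (days) from a delay spec.

    Lognormal delays are parameterised by (mean, CV) via the moment
    identities mu = ln(m / sqrt(1 + cv^2)), sigma = sqrt(ln(1 + cv^2)); a
    zero CV or mean, or the "fixed" family, gives the mean itself.
    """
    m = spec.mean if mean_override is None else mean_override
    if m <= 0.0:
        return max(m, 0.0)
    if spec.family == "fixed" or spec.cv == 0.0:
        return m
    sigma2 = math.log1p(spec.cv**2)
    mu = math.log(m) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Event engine


class _Engine:
    """Minimal event-queue simulator: (time, tie-break, callback) heap."""

    def __init__(self) -> None:
        self.now = 0.0
        self._heap: list = []
        self._seq = itertools.count()

    def schedule(self, time: float, callback) -> None:
        heapq.heappush(self._heap, (time, next(self._seq), callback))

    def run(self) -> None:
        while self._heap:
            time, _, callback = heapq.heappop(self._heap)
            self.now = time
            callback()


class _RolePool:
    """A calendar-constrained server pool with a priority-FCFS queue."""

    def __init__(self, role: str, calendar: CapacityCalendar) -> None:
        self.role = role
        self.calendar = calendar
        self.busy = 0
        self.queue: list = []  # (priority, enqueue_time, seq, service_days, cb)
        self._seq = itertools.count()
        self._next_wake = math.inf
        self.max_queue_len = 0
        self.busy_days = 0.0

    def request(self, engine: _Engine, priority: int, service_days: float, cb) -> None:
        heapq.heappush(
            self.queue, (priority, engine.now, next(self._seq), service_days, cb)
        )
        self.max_queue_len = max(self.max_queue_len, len(self.queue))
        self._dispatch(engine)

    def _dispatch(self, engine: _Engine) -> None:
        t = engine.now
        while self.queue:
            _, _, _, service_days, cb = self.queue[0]
            start = self.calendar.next_feasible_start(self.role, t, service_days)
            if start > t:
                self._wake_at(engine, start)
                return
            if self.busy >= self.calendar.capacity(self.role, t):
                return  # a release will re-dispatch
            heapq.heappop(self.queue)
            self.busy += 1
            self.busy_days += service_days
            end = start + service_days
            engine.schedule(end, self._make_release(engine))
            cb(start, end)

    def _make_release(self, engine: _Engine):
        def release() -> None:
            self.busy -= 1
            self._dispatch(engine)

        return release

    def _wake_at(self, engine: _Engine, time: float) -> None:
        if time < self._next_wake - 1e-12:
            self._next_wake = time

            def wake() -> None:
                self._next_wake = math.inf
                self._dispatch(engine)

            engine.schedule(time, wake)


# ---------------------------------------------------------------------------
# Simulation proper


@dataclass
class _Patient:
    id: int
    pathway: str
    referral_time: float
    priority: int = 0
    comm_method: str | None = None
    stage_times: dict = field(default_factory=dict)
    endpoint_times: dict = field(default_factory=dict)


def estimate_utilization(config: ArmConfig) -> dict[str, float]:
    """Offered load per role: expected service minutes per week over staffed
    minutes per week.  Sustained values near or above 1 are unstable."""
    calendar = build_capacity_calendar(config.staffing, config.weekend_fraction)
    window_min = (calendar.window[1] - calendar.window[0]) * DAY_MINUTES
    per_week_demand: dict[str, float] = {}
    weekly_arrivals = config.arrivals.annual_volume * 7.0 / HORIZON_DAYS
    for pid, p in config.distribution.items():
        for s in config.pathways[pid].stages:
            role = s.activity.role
            if role is not None:
                per_week_demand[role] = (
                    per_week_demand.get(role, 0.0)
                    + weekly_arrivals * p * s.activity.duration
                )
    util = {}
    for role, demand in per_week_demand.items():
        supply = window_min * (
            5 * calendar.weekday_counts.get(role, 0)
            + 2 * calendar.weekend_counts.get(role, 0)
        )
        util[role] = demand / supply if supply > 0 else math.inf
    return util


def infinite_capacity_mean(config: ArmConfig, endpoint: str) -> float:
    """Closed-form expected endpoint time in the no-congestion limit.

    With unconstrained capacity an endpoint time is the sum of the stage
    delay means plus the service durations up to the endpoint stage;
    the arm-level mean weights pathways reaching the endpoint by their
    renormalised proportions.
    """
    mean = mass = 0.0
    for pid, p in config.distribution.items():
        total = 0.0
        reached = False
        for s in config.pathways[pid].stages:
            total += s.delay.mean + s.activity.duration / DAY_MINUTES
            if s.endpoint == endpoint:
                reached = True
                break
        if reached and p > 0:
            mean += p * total
            mass += p
    if mass == 0:
        raise ValueError(f"no pathway with positive mass reaches {endpoint!r}")
    return mean / mass


def simulate_arm(
    config: ArmConfig,
    seed: int,
    horizon: float = HORIZON_DAYS,
    replication: int = 0,
    stability_check: bool = True,
    infinite_capacity: bool = False,
    arrivals_override: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one arm for one replication and return its event log.

    The returned frame has one row per patient with the referral time
    (absolute days), the sampled pathway and communication method, the
    three endpoint times and every stage completion time (``t_<stage>``),
    all endpoint/stage columns in days from the patient's own referral.

    ``infinite_capacity=True`` removes all staffing and shift-window
    constraints (every activity starts the instant its wait elapses) —
    the no-congestion limit used by the calibrator's analytic phase and
    the closed-form oracles.
    """
    if stability_check and not infinite_capacity:
        unstable = {r: u for r, u in estimate_utilization(config).items() if u > 0.9}
        if unstable:
            warnings.warn(
                f"offered load exceeds 0.9 for role(s) {unstable}; queues may "
                "grow without bound (queue-growth diagnostics are in the log "
                "attrs)",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    calendar = build_capacity_calendar(config.staffing, config.weekend_fraction)
    engine = _Engine()
    pools = {role: _RolePool(role, calendar) for role in config.roles}

    if arrivals_override is not None:
        arrivals = np.asarray(arrivals_override, dtype=float)
    else:
        arrivals = generate_arrivals(config.arrivals, rng, horizon)
    norm = config.distribution.normalized()
    ids = sorted(norm)
    probs = np.array([norm[pid] for pid in ids])
    pathway_draw = rng.choice(len(ids), size=arrivals.size, p=probs)

    records: list[_Patient] = []

    def comm_mean(patient: _Patient, stage: Stage) -> float:
        """Sample the communication method; rescale the stage delay mean so
        the method mixture's mean equals the configured pathway mean."""
        mix = config.comm_mix.get(patient.pathway)
        if not mix:
            return stage.delay.mean
        methods = sorted(mix)
        fracs = np.array([mix[m] for m in methods])
        method = methods[rng.choice(len(methods), p=fracs)]
        patient.comm_method = method
        rels = {m: config.comm_methods[m].rel_mean for m in methods}
        mixture_rel = sum(mix[m] * rels[m] for m in methods)
        return stage.delay.mean * rels[method] / mixture_rel

    def advance(patient: _Patient, stage_idx: int, t_done: float) -> None:
        stages = config.pathways[patient.pathway].stages
        if stage_idx >= len(stages):
            records.append(patient)
            return
        stage = stages[stage_idx]
        override = comm_mean(patient, stage) if stage.name == "communication" else None
        ready = t_done + sample_delay(stage.delay, rng, mean_override=override)
        activity = stage.activity

        def complete(start: float, end: float) -> None:
            patient.stage_times[stage.name] = end - patient.referral_time
            if stage.endpoint is not None:
                patient.endpoint_times[stage.endpoint] = end - patient.referral_time
            advance(patient, stage_idx + 1, end)

        service_days = activity.duration / DAY_MINUTES
        if activity.role is None or infinite_capacity:
            engine.schedule(ready, lambda: complete(ready, ready + service_days))
        else:
            pool = pools[activity.role]
            engine.schedule(
                ready,
                lambda: pool.request(engine, patient.priority, service_days, complete),
            )

    for i, (t0, k) in enumerate(zip(arrivals, pathway_draw)):
        patient = _Patient(id=i, pathway=ids[k], referral_time=float(t0))
        advance(patient, 0, float(t0))

    engine.run()  # run to drain: all agents exit past the horizon

    rows = []
    for p in sorted(records, key=lambda p: p.id):
        row = {
            "patient_id": p.id,
            "replication": replication,
            "arm": config.arm,
            "pathway": p.pathway,
            "referral_time": p.referral_time,
            "priority": p.priority,
            "comm_method": p.comm_method,
        }
        for ep in ENDPOINTS:
            row[ep] = p.endpoint_times.get(ep, np.nan)
        for name, t in p.stage_times.items():
            row[f"t_{name}"] = t
        rows.append(row)
    log = pd.DataFrame(rows)
    log.attrs["max_queue_len"] = {r: pool.max_queue_len for r, pool in pools.items()}
    log.attrs["seed"] = seed
    return log


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class EndpointStats:
    """Mean waiting time with its sampling uncertainty, for one endpoint."""

    mean: float
    se: float
    ci95: tuple[float, float]
    max: float
    n: int


@dataclass(frozen=True)
class SimulationSummary:
    """Per-endpoint and per-pathway waiting-time statistics of an event log."""

    endpoints: dict[str, EndpointStats]
    pathway_endpoints: dict[str, dict[str, EndpointStats]]
    n_patients: int
    n_replications: int


def _stats(values: np.ndarray) -> EndpointStats:
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return EndpointStats(
        mean=mean,
        se=se,
        ci95=(mean - 1.96 * se, mean + 1.96 * se),
        max=float(values.max()),
        n=n,
    )


def summarize_endpoints(log: pd.DataFrame) -> SimulationSummary:
    """Per-endpoint mean/SE/95% CI/max, pooled at patient level.

    The histopathology endpoint is computed only over patients on
    biopsy-reliant pathways; an endpoint with no eligible patients is
    absent from the result rather than reported as zero.
    """
    if log.empty:
        raise ValueError("event log is empty")
    endpoints = {}
    for ep in ENDPOINTS:
        values = log[ep].dropna().to_numpy()
        if values.size:
            endpoints[ep] = _stats(values)
    pathway_endpoints: dict[str, dict[str, EndpointStats]] = {}
    for pid, group in log.groupby("pathway"):
        pathway_endpoints[pid] = {}
        for ep in ENDPOINTS:
            values = group[ep].dropna().to_numpy()
            if values.size:
                pathway_endpoints[pid][ep] = _stats(values)
    return SimulationSummary(
        endpoints=endpoints,
        pathway_endpoints=pathway_endpoints,
        n_patients=int(len(log)),
        n_replications=int(log["replication"].nunique()),
    )


def replicate(
    config: ArmConfig,
    n_runs: int = 5,
    master_seed: int = 0,
    horizon: float = HORIZON_DAYS,
) -> tuple[pd.DataFrame, SimulationSummary]:
    """Run independent 1-year replications and pool them at patient level.

    Per-replication seeds are derived from the master seed; a single run
    reproduces :func:`simulate_arm` under the derived seed exactly.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    seeds = derive_seeds(master_seed, n_runs)
    logs = [
        simulate_arm(config, seed=s, horizon=horizon, replication=r)
        for r, s in enumerate(seeds)
    ]
    pooled = pd.concat(logs, ignore_index=True)
    pooled.attrs["seeds"] = seeds
    return pooled, summarize_endpoints(pooled)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replication seeds from a master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n)]


def weighted_average_time(
    pathway_means: dict[str, tuple[float, float]],
    dist: ArmDistribution,
) -> tuple[float, float]:
    """Pathway-proportion-weighted mean time and its propagated SE.

    ``pathway_means`` maps pathway id → (mean, SE).  Every pathway with a
    positive proportion must have a mean; SEs combine as
    ``sqrt(sum_i p_i^2 se_i^2)`` (independent per-pathway estimates).
    """
    mean = 0.0
    var = 0.0
    for pid, p in dist.items():
        if p == 0.0:
            continue
        if pid not in pathway_means:
            raise KeyError(f"no mean supplied for represented pathway {pid!r}")
        m, se = pathway_means[pid]
        mean += p * m
        var += (p * se) ** 2
    return mean, math.sqrt(var)


def incremental_times(
    intervention: SimulationSummary,
    comparator: SimulationSummary,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Comparator-minus-intervention mean waiting-time difference per endpoint.

    Returns endpoint → (delta, 95% CI), the CI from the combined SEs under
    a normal approximation; endpoints absent from either arm are omitted.
    """
    out = {}
    for ep in ENDPOINTS:
        if ep in intervention.endpoints and ep in comparator.endpoints:
            a = comparator.endpoints[ep]
            b = intervention.endpoints[ep]
            delta = a.mean - b.mean
            se = math.hypot(a.se, b.se)
            out[ep] = (delta, (delta - 1.96 * se, delta + 1.96 * se))
    return out
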