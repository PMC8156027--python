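"""Discrete-event protocol engine for manual and automated conditioning.

The engine runs a complete training study for one simulated subject: the
pre-training gate, then a ladder of discriminations of increasing
difficulty (3v12 -> 2v3 -> 3v4 -> 4v5 -> 5v6, or the shape/color/size
sequence of the reduced-load variant), advancing only when a learning
criterion is met and stopping at the first failure.

Protocol rules implemented:

* manual mode: 12 analyzable trials per day (6 morning + 6 afternoon,
  15-min inter-trial and 90-min inter-session intervals), reward only when
  the first approach is to the larger numerosity, no correction trials;
* automated mode: sessions capped by wall time (60 min; 8 h in the spaced
  variant) and by a daily maximum of 80 reinforcements; a second daily
  session (after a 2-h break) if and only if the first yields fewer than
  40 reinforcements, with its cap reduced by the rewards already obtained;
  errors blank the screen and trigger correction trials — the same pair in
  the same left/right position after the correction interval, repeated
  until the subject is correct (with a safeguard cap against pathological
  agents) — which are logged but excluded from every accuracy tally;
* side scheduling: uniform random left/right with no run of three
  identical correct sides;
* learning criteria: primary — at least 75% correct pooled over two
  consecutive days; secondary — at least 60% correct over all trials of
  the contrast, significant by an exact binomial test (87/144 for 3 vs 12,
  72/120 for the later 10-day contrasts).

Time is a simulated per-day clock in seconds; agent locomotion enters only
as a decision latency drawn from the agent's lognormal model scaled by the
chamber's start->choice distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .agents import Agent, AgentParams
from .chamber import chamber_geometry
from .stats import binom_two_sided
from .stimuli import CONTRASTS, FEATURE_TASKS, rotation_order

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "SessionRecord",
    "CriterionResult",
    "GateResult",
    "SubjectRun",
    "correct_side_sequence",
    "side_schedule",
    "run_trial",
    "run_automated_session",
    "run_automated_day",
    "run_manual_day",
    "primary_criterion",
    "secondary_criterion",
    "run_contrast",
    "pretraining_gate",
    "run_ladder",
    "task_kind",
    "PRESET_NAMES",
]

PRESET_NAMES = ("exp1_manual", "exp1_auto", "exp2", "exp3A", "exp3B",
                "exp4A", "exp4B", "exp5")

# Baseline start->choice distance (variant B) against which decision
# latencies scale; the manual tank's stimulus approach is ~22 cm.
_BASE_DISTANCE = 6.0
_MANUAL_DISTANCE = 22.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Full specification of one training regime."""

    name: str = "exp1_auto"
    mode: str = "automated"                  # "manual" | "automated"
    chamber_variant: str = "B"               # B | C | D | E (automated only)
    position_scheme: str = "fixed"           # "fixed" | "varied18"
    ladder: tuple = ("3v12", "2v3", "3v4", "4v5", "5v6")
    max_days: dict = field(default_factory=lambda: {"3v12": 12, "default": 10})
    trials_per_day: int = 12                 # manual mode (6 + 6)
    intertrial_minutes: float = 15.0         # manual
    intersession_minutes: float = 90.0       # manual 90, automated 120
    session_minutes: float = 60.0            # automated training session cap
    pretraining_session_minutes: float = 30.0
    daily_reinforcement_cap: int = 80
    low_yield_threshold: int = 40
    correction_interval_s: float = 10.0
    max_corrections: int = 30
    resident: bool = False
    context_load: float = 0.0
    primary_accuracy: float = 0.75
    primary_mode: str = "pooled"             # "pooled" | "per_day"
    secondary_accuracy: float = 0.60
    alpha: float = 0.05
    pretraining: dict = field(default_factory=lambda: {
        "type": "auto", "reward_target": 30, "max_sessions": 12,
        "per_day_pair": True})
    handling_s: float = 2.0                  # stimulus onset/feeder overhead

    def __post_init__(self):
        if self.mode not in ("manual", "automated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for f_ in ("session_minutes", "pretraining_session_minutes",
                   "correction_interval_s", "intersession_minutes"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")
        if self.daily_reinforcement_cap <= 0 or self.low_yield_threshold <= 0:
            raise ValueError("reinforcement caps must be positive")
        if self.trials_per_day % 2:
            raise ValueError("manual trials_per_day must be even for "
                             "side counterbalancing")

    def max_days_for(self, task: str) -> int:
        return int(self.max_days.get(task, self.max_days.get("default", 10)))

    def distance_scale(self) -> float:
        if self.mode == "manual":
            return _MANUAL_DISTANCE / _BASE_DISTANCE
        geom = chamber_geometry(self.chamber_variant)
        return geom.start_choice_distance / _BASE_DISTANCE


def task_kind(task: str) -> tuple:
    """Resolve a ladder entry: returns ('numerical', (nS, nL)) or
    ('feature', kind)."""
    if task in CONTRASTS:
        return ("numerical", CONTRASTS[task])
    if task in FEATURE_TASKS:
        return ("feature", task)
    raise ValueError(f"unknown task {task!r}")


def _set_size(task: str) -> int:
    if task == "3v12":
        return 18
    if task in CONTRASTS:
        return 24
    return 1


@dataclass(frozen=True)
class TrialRecord:
    index: int                 # analyzable-trial index within the contrast
    day: int
    session: int
    task: str
    pair_id: str
    placement_index: int
    correct_side: str
    chosen_side: str
    correct: bool
    is_correction: bool
    latency_s: float
    t_start: float             # seconds from session start
    t_end: float
    correction_overflow: bool = False


@dataclass
class SessionRecord:
    day: int
    index: int                 # session index within the day
    phase: str                 # "pretraining" | "training"
    task: str
    trials: list = field(default_factory=list)
    reinforcements: int = 0
    duration_s: float = 0.0

    def analyzable(self) -> list:
        return [t for t in self.trials if not t.is_correction]

    def tally(self) -> tuple[int, int]:
        a = self.analyzable()
        return sum(t.correct for t in a), len(a)


@dataclass(frozen=True)
class CriterionResult:
    outcome: str               # "primary" | "secondary" | "failed"
    trials_to_criterion: int | None
    days_to_criterion: int | None

    def __post_init__(self):
        present = self.trials_to_criterion is not None \
            and self.days_to_criterion is not None
        if (self.outcome == "failed") == present:
            raise ValueError("trials/days must be present iff criterion met")


@dataclass(frozen=True)
class GateResult:
    passed: bool
    sessions: int
    rewards: tuple
    detail: str = ""


@dataclass
class SubjectRun:
    subject_id: str
    preset: str
    seed: int
    params: AgentParams
    gate: GateResult | None = None
    results: dict = field(default_factory=dict)    # task -> CriterionResult
    sessions: list = field(default_factory=list)   # SessionRecord, in order

    def tasks_passed(self) -> list:
        return [t for t, r in self.results.items() if r.outcome != "failed"]


# ---------------------------------------------------------------------------
# side scheduling

def correct_side_sequence(n: int, seed=None) -> list:
    """Uniform-random left/right sequence with no run of three identical
    sides, by redrawing any side that would complete a triple."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list = []
    for _ in range(n):
        while True:
            s = "left" if rng.random() < 0.5 else "right"
            if len(out) >= 2 and out[-1] == out[-2] == s:
                continue
            out.append(s)
            break
    return out


def side_schedule(rng: np.random.Generator):
    """Infinite max-run-2 side stream sharing one RNG."""
    last = [None, None]
    while True:
        while True:
            s = "left" if rng.random() < 0.5 else "right"
            if not (last[0] == last[1] == s):
                break
        last = [last[1], s]
        yield s


def _counterbalanced_sides(n: int, rng: np.random.Generator) -> list:
    """Exactly n/2 left and n/2 right in random order with no run of 3."""
    base = ["left"] * (n // 2) + ["right"] * (n // 2)
    for _ in range(10_000):
        rng.shuffle(base)
        if all(not (base[i] == base[i + 1] == base[i + 2])
               for i in range(n - 2)):
            return list(base)
    raise RuntimeError("could not counterbalance sides")  # pragma: no cover


# ---------------------------------------------------------------------------
# trials and sessions

def _placement_for(config: ProtocolConfig, trial_index: int) -> int:
    if config.position_scheme == "varied18":
        return rotation_order(trial_index + 1)[-1]
    return 0


def run_trial(agent: Agent, task: str, pair_id: str, placement: int,
              correct_side: str, config: ProtocolConfig, clock: float,
              session_end: float, index: int, day: int, session: int,
              ) -> tuple[list, float, int]:
    """Run one analyzable trial plus its correction sub-loop.

    Returns (records, new_clock, reinforcements_delivered). The analyzable
    record is always first; corrections repeat the same pair and placement
    until the subject is correct, the safeguard cap is hit, or the session
    clock runs out.
    """
    kind, payload = task_kind(task)
    stim = payload if kind == "numerical" else task
    records: list = []
    lat = agent.latency(config.distance_scale())
    t0 = clock
    clock = clock + config.handling_s + lat
    side = agent.choose(stim, correct_side, config.context_load)
    correct = side == correct_side
    agent.update(correct)
    rewards = int(correct)
    records.append(TrialRecord(index, day, session, task, pair_id, placement,
                               correct_side, side, correct, False, lat, t0,
                               clock))
    if correct or config.mode == "manual":
        return records, clock, rewards
    # correction loop (automated mode only)
    overflow = True
    for _c in range(config.max_corrections):
        clock += config.correction_interval_s
        if clock >= session_end:
            overflow = False  # session ran out, not a pathological agent
            break
        lat = agent.latency(config.distance_scale())
        t0 = clock
        clock += lat
        side = agent.choose(stim, correct_side, config.context_load)
        correct = side == correct_side
        agent.update(correct)
        records.append(TrialRecord(index, day, session, task, pair_id,
                                   placement, correct_side, side, correct,
                                   True, lat, t0, clock))
        if correct:
            rewards += 1
            overflow = False
            break
    if overflow and records:
        records[-1] = replace(records[-1], correction_overflow=True)
    return records, clock, rewards


def run_automated_session(agent: Agent, task: str, config: ProtocolConfig,
                          sides, stim_rng: np.random.Generator, day: int,
                          session_index: int, session_cap: int,
                          start_index: int,
                          session_minutes: float | None = None,
                          ) -> SessionRecord:
    """One automated training session: trials until the reinforcement cap
    or the session clock expires."""
    minutes = config.session_minutes if session_minutes is None else session_minutes
    session_end = minutes * 60.0
    rec = SessionRecord(day, session_index, "training", task)
    clock = 0.0
    n_pairs = _set_size(task)
    index = start_index
    while rec.reinforcements < session_cap:
        # peek: does another trial fit before the clock runs out?
        if clock + config.handling_s >= session_end:
            break
        pair_id = f"{task}-{int(stim_rng.integers(n_pairs)):02d}"
        placement = _placement_for(config, index)
        records, clock, rewards = run_trial(
            agent, task, pair_id, placement, next(sides), config, clock,
            session_end, index, day, session_index)
        if records[0].t_end > session_end:
            # the trial outlasted the session: drop it, the session is over
            break
        rec.trials.extend(records)
        rec.reinforcements += rewards
        index += 1
    rec.duration_s = min(clock, session_end)
    return rec


def run_automated_day(agent: Agent, task: str, config: ProtocolConfig,
                      sides, stim_rng: np.random.Generator, day: int,
                      start_index: int) -> list:
    """One automated training day: a second session happens iff the first
    yields fewer than ``low_yield_threshold`` reinforcements, with its cap
    reduced to the daily remainder."""
    s1 = run_automated_session(agent, task, config, sides, stim_rng, day, 1,
                               config.daily_reinforcement_cap, start_index)
    sessions = [s1]
    if s1.reinforcements < config.low_yield_threshold:
        cap2 = config.daily_reinforcement_cap - s1.reinforcements
        s2 = run_automated_session(agent, task, config, sides, stim_rng, day,
                                   2, cap2,
                                   start_index + len(s1.analyzable()))
        sessions.append(s2)
    return sessions


def run_manual_day(agent: Agent, task: str, config: ProtocolConfig,
                   side_rng: np.random.Generator,
                   stim_rng: np.random.Generator, day: int,
                   start_index: int) -> list:
    """One manual training day: two sessions of trials_per_day/2 trials,
    correct sides counterbalanced across the day, reward iff the first
    approach is to the larger numerosity."""
    n = config.trials_per_day
    day_sides = _counterbalanced_sides(n, side_rng)
    half = n // 2
    n_pairs = _set_size(task)
    sessions = []
    index = start_index
    for si, chunk in enumerate((day_sides[:half], day_sides[half:]), start=1):
        rec = SessionRecord(day, si, "training", task)
        clock = 0.0
        for correct_side in chunk:
            pair_id = f"{task}-{int(stim_rng.integers(n_pairs)):02d}"
            records, clock, rewards = run_trial(
                agent, task, pair_id, 0, correct_side, config, clock,
                math.inf, index, day, si)
            rec.trials.extend(records)
            rec.reinforcements += rewards
            clock += config.intertrial_minutes * 60.0
            index += 1
        rec.duration_s = clock
        sessions.append(rec)
    return sessions


# ---------------------------------------------------------------------------
# learning criteria

def primary_criterion(daily_tallies, threshold: float = 0.75,
                      mode: str = "pooled") -> bool:
    """True when any two consecutive days reach the accuracy threshold
    (pooled over the 2-day window by default, or on each day separately)."""
    tallies = [(int(k), int(n)) for k, n in daily_tallies]
    if not tallies:
        raise ValueError("empty daily tallies")
    for (k1, n1), (k2, n2) in zip(tallies, tallies[1:]):
        if n1 == 0 or n2 == 0:
            continue
        if mode == "pooled":
            if (k1 + k2) / (n1 + n2) >= threshold:
                return True
        elif mode == "per_day":
            if k1 / n1 >= threshold and k2 / n2 >= threshold:
                return True
        else:
            raise ValueError(f"unknown primary mode {mode!r}")
    return False


def secondary_criterion(correct: int, total: int, alpha: float = 0.05,
                        min_accuracy: float = 0.60) -> bool:
    """True when overall accuracy is at least 60% and differs from chance
    by an exact two-sided binomial test at level alpha."""
    if total < 1:
        raise ValueError("empty tally")
    if correct / total < min_accuracy:
        return False
    return binom_two_sided(correct, total, 0.5).pvalue < alpha


# ---------------------------------------------------------------------------
# contrast, gate, ladder

def run_contrast(agent: Agent, task: str, config: ProtocolConfig,
                 side_stream_rng: np.random.Generator,
                 stim_rng: np.random.Generator,
                 ) -> tuple[CriterionResult, list]:
    """Train one contrast to criterion or to its day cap."""
    sessions: list = []
    daily: list = []
    total_k = total_n = 0
    sides = side_schedule(side_stream_rng)
    for day in range(1, config.max_days_for(task) + 1):
        if config.mode == "manual":
            day_sessions = run_manual_day(agent, task, config,
                                          side_stream_rng, stim_rng, day,
                                          total_n)
        else:
            day_sessions = run_automated_day(agent, task, config, sides,
                                             stim_rng, day, total_n)
        sessions.extend(day_sessions)
        k = sum(s.tally()[0] for s in day_sessions)
        n = sum(s.tally()[1] for s in day_sessions)
        daily.append((k, n))
        total_k += k
        total_n += n
        if len(daily) >= 2 and n > 0 and primary_criterion(
                daily[-2:], config.primary_accuracy, config.primary_mode):
            return CriterionResult("primary", total_n, day), sessions
    if total_n > 0 and secondary_criterion(total_k, total_n, config.alpha,
                                           config.secondary_accuracy):
        return CriterionResult("secondary", total_n, len(daily)), sessions
    return CriterionResult("failed", None, None), sessions


def _pretraining_session(agent: Agent, config: ProtocolConfig, day: int,
                         index: int, minutes: float,
                         latency_factor: float = 1.0) -> SessionRecord:
    """A pre-training session: every completed shuttle cycle is rewarded,
    up to the daily reinforcement cap."""
    rec = SessionRecord(day, index, "pretraining", "pretraining")
    end = minutes * 60.0
    clock = 0.0
    # Pre-training shuttle cycles involve no stimulus evaluation, so they
    # run at the base latency regardless of chamber size; only the barrier
    # detour (latency_factor) slows them.
    while rec.reinforcements < config.daily_reinforcement_cap:
        lat = agent.latency(latency_factor)
        if clock + config.handling_s + lat > end:
            break
        clock += config.handling_s + lat
        rec.reinforcements += 1
    rec.duration_s = min(clock, end)
    return rec


def pretraining_gate(agent: Agent, config: ProtocolConfig,
                     ) -> tuple[GateResult, list]:
    """Admission gate before training.

    manual: pass iff the subject approaches the card on all 12
    presentations of the second pre-training day.
    auto: pass iff a same-day pair of 30-min sessions yields at least 30
    rewards in total, evaluated over at most 12 sessions.
    barrier: first learn to detour a narrow barrier (one session with at
    least 30 rewards), then pass the standard two-session rule with the
    wide training barrier; the 12-session budget is shared.
    ramp: the standard auto gate followed by a habituation day of four
    sessions of 15/30/45/60 minutes.
    """
    kind = config.pretraining.get("type", "auto")
    target = int(config.pretraining.get("reward_target", 30))
    max_sessions = int(config.pretraining.get("max_sessions", 12))
    sessions: list = []

    if kind == "manual":
        day2 = [agent.approaches_card() for _ in range(12)]
        rec = SessionRecord(2, 1, "pretraining", "pretraining")
        rec.reinforcements = sum(day2)
        sessions.append(rec)
        ok = all(day2)
        return GateResult(ok, 1, (sum(day2),),
                          "12/12 approaches required on day 2"), sessions

    def run_pair_gate(start_session: int, latency_factor: float = 1.0):
        rewards = []
        s = start_session
        while s + 2 <= max_sessions:
            day = (s + 1) // 2 + 1
            r1 = _pretraining_session(agent, config, day, 1,
                                      config.pretraining_session_minutes,
                                      latency_factor)
            r2 = _pretraining_session(agent, config, day, 2,
                                      config.pretraining_session_minutes,
                                      latency_factor)
            sessions.extend([r1, r2])
            rewards.extend([r1.reinforcements, r2.reinforcements])
            s += 2
            if r1.reinforcements + r2.reinforcements >= target:
                return True, s, rewards
        return False, s, rewards

    if kind == "auto":
        ok, used, rewards = run_pair_gate(0)
        return GateResult(ok, used, tuple(rewards),
                          f">= {target} rewards over a session pair"), sessions

    if kind == "barrier":
        # stage 1: 7 x 10 cm barrier, pass on a single >= target session
        factor_narrow = float(config.pretraining.get("narrow_factor", 1.5))
        factor_wide = float(config.pretraining.get("wide_factor", 1.8))
        used = 0
        stage1_rewards = []
        stage1_ok = False
        while used < max_sessions:
            r = _pretraining_session(agent, config, used // 2 + 1,
                                     used % 2 + 1,
                                     config.pretraining_session_minutes,
                                     factor_narrow)
            sessions.append(r)
            stage1_rewards.append(r.reinforcements)
            used += 1
            if r.reinforcements >= target:
                stage1_ok = True
                break
        if not stage1_ok:
            return GateResult(False, used, tuple(stage1_rewards),
                              "failed narrow-barrier stage"), sessions
        ok, used, rewards = run_pair_gate(used, factor_wide)
        return GateResult(ok, used, tuple(stage1_rewards + rewards),
                          "barrier detour then session-pair rule"), sessions

    if kind == "ramp":
        ok, used, rewards = run_pair_gate(0)
        ramp = []
        if ok:
            day = used // 2 + 2
            for i, minutes in enumerate((15.0, 30.0, 45.0, 60.0), start=1):
                r = _pretraining_session(agent, config, day, i, minutes)
                sessions.append(r)
                ramp.append(r.reinforcements)
        return GateResult(ok, used + len(ramp), tuple(rewards + ramp),
                          "session-pair rule plus 15/30/45/60-min ramp day"), sessions

    raise ValueError(f"unknown pretraining type {kind!r}")


def run_ladder(params: AgentParams, config: ProtocolConfig, seed: int,
               subject_id: str = "S1", skip_gate: bool = False) -> SubjectRun:
    """Run one subject through pre-training and the full task ladder.

    Bit-reproducible given (params, config, seed): the master seed splits
    into independent streams for side scheduling, stimulus sampling, and
    agent behavior.
    """
    ss = np.random.SeedSequence(seed)
    agent_ss, side_ss, stim_ss = ss.spawn(3)
    agent = Agent(params, seed=agent_ss)
    run = SubjectRun(subject_id, config.name, seed, params)
    if not skip_gate:
        gate, gate_sessions = pretraining_gate(agent, config)
        run.gate = gate
        run.sessions.extend(gate_sessions)
        if not gate.passed:
            return run
    for task, task_side_ss, task_stim_ss in zip(
            config.ladder, side_ss.spawn(len(config.ladder)),
            stim_ss.spawn(len(config.ladder))):
        result, sessions = run_contrast(
            agent, task, config, np.random.default_rng(task_side_ss),
            np.random.default_rng(task_stim_ss))
        run.results[task] = result
        run.sessions.extend(sessions)
        if result.outcome == "failed":
            break
    return run
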