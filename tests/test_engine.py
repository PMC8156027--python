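"""Tests for the trial/session protocol engine."""

import dataclasses
import math

import numpy as np
import pytest

from skinnertank.agents import (Agent, AgentParams, always_left_agent,
                                chance_agent, perfect_agent)
from skinnertank.engine import (CriterionResult, ProtocolConfig,
                                correct_side_sequence, pretraining_gate,
                                primary_criterion, run_automated_day,
                                run_ladder, run_manual_day, run_trial,
                                secondary_criterion, side_schedule)
from skinnertank.io import load_preset


def daily_tallies(run, task):
    """(correct, total) per day for a task, excluding corrections."""
    days = {}
    for s in run.sessions:
        if s.task == task and s.phase == "training":
            k, n = s.tally()
            pk, pn = days.get(s.day, (0, 0))
            days[s.day] = (pk + k, pn + n)
    return [days[d] for d in sorted(days)]


def daily_reinforcements(run):
    days = {}
    for s in run.sessions:
        if s.phase == "training":
            key = (s.task, s.day)
            days[key] = days.get(key, 0) + s.reinforcements
    return days


class TestSideScheduling:
    def test_no_run_of_three_in_long_sequence(self):
        seq = correct_side_sequence(10_000, seed=1)
        assert all(not (seq[i] == seq[i + 1] == seq[i + 2])
                   for i in range(len(seq) - 2))

    def test_single_trial(self):
        assert correct_side_sequence(1, seed=0)[0] in ("left", "right")

    def test_length_three_support_is_exactly_six_sequences(self):
        # enumeration oracle: the rejection rule admits exactly the 6 of 8
        # length-3 sequences without a triple
        seen = {tuple(correct_side_sequence(3, seed=s)) for s in range(300)}
        all_seqs = {(a, b, c) for a in ("left", "right")
                    for b in ("left", "right") for c in ("left", "right")}
        valid = {s for s in all_seqs if not (s[0] == s[1] == s[2])}
        assert seen == valid

    def test_infinite_stream_matches_constraint(self):
        gen = side_schedule(np.random.default_rng(2))
        seq = [next(gen) for _ in range(5000)]
        assert all(not (seq[i] == seq[i + 1] == seq[i + 2])
                   for i in range(len(seq) - 2))


class TestTrials:
    def test_correct_agent_single_rewarded_record(self):
        cfg = load_preset("exp1_auto")
        agent = Agent(perfect_agent(), seed=0)
        records, clock, rewards = run_trial(
            agent, "3v12", "3v12-00", 0, "left", cfg, 0.0, 3600.0, 0, 1, 1)
        assert len(records) == 1 and records[0].correct and rewards == 1
        assert not records[0].is_correction

    def test_always_left_agent_hits_correction_safeguard(self):
        cfg = load_preset("exp1_auto")
        agent = Agent(always_left_agent(), seed=0)
        records, clock, rewards = run_trial(
            agent, "3v12", "3v12-00", 0, "right", cfg, 0.0, math.inf, 0, 1, 1)
        corrections = [r for r in records if r.is_correction]
        assert len(corrections) == cfg.max_corrections
        assert records[-1].correction_overflow
        assert rewards == 0
        # corrections repeat the pair and placement
        assert {r.pair_id for r in records} == {"3v12-00"}
        assert {r.placement_index for r in records} == {0}

    def test_corrections_terminate_on_correct_choice(self):
        cfg = load_preset("exp1_auto")
        agent = Agent(chance_agent(), seed=5)
        records, clock, rewards = run_trial(
            agent, "3v12", "3v12-00", 0, "right", cfg, 0.0, math.inf, 0, 1, 1)
        if records[0].correct:
            assert len(records) == 1
        else:
            assert records[-1].correct and records[-1].is_correction
            assert rewards == 1

    def test_manual_mode_has_no_corrections(self):
        cfg = load_preset("exp1_manual")
        agent = Agent(always_left_agent(), seed=0)
        records, clock, rewards = run_trial(
            agent, "3v12", "3v12-00", 0, "right", cfg, 0.0, math.inf, 0, 1, 1)
        assert len(records) == 1 and rewards == 0


class TestDays:
    def test_fast_accurate_agent_single_session_at_cap(self):
        cfg = load_preset("exp1_auto")
        agent = Agent(dataclasses.replace(perfect_agent(),
                                          latency_median_s=20.0), seed=1)
        sides = side_schedule(np.random.default_rng(0))
        sessions = run_automated_day(agent, "3v12", cfg, sides,
                                     np.random.default_rng(1), 1, 0)
        assert len(sessions) == 1
        assert sessions[0].reinforcements == 80

    def test_slow_agent_gets_second_session_with_remainder_cap(self):
        cfg = load_preset("exp1_auto")
        # latency tuned so session 1 yields well under 40 rewards
        agent = Agent(AgentParams(weber=1e-3, lapse=0.0, q0=1.0,
                                  acquisition=0.0, load_penalty=0.0,
                                  latency_median_s=140.0, latency_sigma=0.01),
                      seed=2)
        sides = side_schedule(np.random.default_rng(0))
        sessions = run_automated_day(agent, "3v12", cfg, sides,
                                     np.random.default_rng(1), 1, 0)
        assert len(sessions) == 2
        r1 = sessions[0].reinforcements
        assert r1 < 40
        assert sessions[0].reinforcements + sessions[1].reinforcements <= 80

    def test_zero_activity_agent_two_empty_sessions(self):
        cfg = load_preset("exp1_auto")
        agent = Agent(AgentParams(latency_median_s=30_000.0), seed=0)
        sides = side_schedule(np.random.default_rng(0))
        sessions = run_automated_day(agent, "3v12", cfg, sides,
                                     np.random.default_rng(1), 1, 0)
        assert len(sessions) == 2
        assert all(s.reinforcements == 0 for s in sessions)

    def test_manual_day_structure(self):
        cfg = load_preset("exp1_manual")
        agent = Agent(perfect_agent(), seed=3)
        sessions = run_manual_day(agent, "3v12", cfg,
                                  np.random.default_rng(1),
                                  np.random.default_rng(2), 1, 0)
        trials = [t for s in sessions for t in s.trials]
        assert len(sessions) == 2
        assert len(trials) == 12
        sides = [t.correct_side for t in trials]
        assert sides.count("left") == 6 and sides.count("right") == 6
        # reward iff first approach is to the larger numerosity
        assert all(t.correct for t in trials)
        assert sum(s.reinforcements for s in sessions) == 12


class TestCriteria:
    def test_primary_pooled_18_of_24(self):
        assert primary_criterion([(9, 12), (9, 12)])
        assert not primary_criterion([(8, 12), (9, 12)])
        assert primary_criterion([(3, 12), (8, 12), (10, 12)])

    def test_primary_per_day_mode(self):
        assert not primary_criterion([(11, 12), (8, 12)], mode="per_day")
        assert primary_criterion([(9, 12), (9, 12)], mode="per_day")

    def test_primary_empty_rejected(self):
        with pytest.raises(ValueError):
            primary_criterion([])

    def test_secondary_thresholds(self):
        assert secondary_criterion(87, 144)
        assert secondary_criterion(72, 120)
        assert not secondary_criterion(60, 120)   # exactly chance
        assert not secondary_criterion(86, 144)   # below 60%

    def test_criterion_result_field_consistency(self):
        with pytest.raises(ValueError):
            CriterionResult("failed", 100, 5)
        with pytest.raises(ValueError):
            CriterionResult("primary", None, None)


class TestLadder:
    def test_perfect_agent_passes_at_earliest_manual_point(self):
        run = run_ladder(perfect_agent(), load_preset("exp1_manual"), seed=1)
        res = run.results["3v12"]
        assert res.outcome == "primary"
        assert res.days_to_criterion == 2
        assert res.trials_to_criterion == 24

    def test_ladder_order_never_skips(self):
        run = run_ladder(AgentParams(), load_preset("exp1_manual"), seed=4)
        tasks = list(run.results)
        expected = ["3v12", "2v3", "3v4", "4v5", "5v6"]
        assert tasks == expected[:len(tasks)]
        # a failure, when present, is the final entry
        outcomes = [r.outcome for r in run.results.values()]
        assert all(o != "failed" for o in outcomes[:-1])

    def test_correction_trials_never_enter_accuracy(self):
        run = run_ladder(AgentParams(), load_preset("exp1_auto"), seed=6)
        for s in run.sessions:
            if s.phase != "training":
                continue
            k, n = s.tally()
            with_corr = sum(t.correct for t in s.trials)
            assert n == len([t for t in s.trials if not t.is_correction])
            if any(t.is_correction for t in s.trials):
                # correction runs end in a correct choice, so including
                # them changes the tally
                assert with_corr > k

    def test_daily_cap_never_exceeded(self):
        run = run_ladder(AgentParams(), load_preset("exp1_auto"), seed=7)
        assert run.sessions
        assert max(daily_reinforcements(run).values()) <= 80

    def test_bit_reproducible_given_seed(self):
        r1 = run_ladder(AgentParams(), load_preset("exp1_auto"), seed=9)
        r2 = run_ladder(AgentParams(), load_preset("exp1_auto"), seed=9)
        t1 = [t for s in r1.sessions for t in s.trials]
        t2 = [t for s in r2.sessions for t in s.trials]
        assert t1 == t2
        assert r1.results == r2.results

    def test_accuracy_decreases_with_lapse(self):
        # trials-to-criterion monotonicity surrogate: mean accuracy on the
        # easiest contrast falls as the lapse rate rises (seeds averaged)
        def mean_acc(lapse):
            accs = []
            for seed in range(8):
                run = run_ladder(AgentParams(lapse=lapse, q0=1.0),
                                 load_preset("exp1_manual"), seed=seed,
                                 skip_gate=True)
                tal = daily_tallies(run, "3v12")
                k = sum(t[0] for t in tal)
                n = sum(t[1] for t in tal)
                accs.append(k / n)
            return np.mean(accs)

        assert mean_acc(0.0) > mean_acc(0.4) > mean_acc(0.8)


class TestPretraining:
    def test_default_agent_passes_auto_gate_quickly(self):
        agent = Agent(AgentParams(), seed=1)
        gate, sessions = pretraining_gate(agent, load_preset("exp1_auto"))
        assert gate.passed
        assert sum(gate.rewards[:2]) >= 30

    def test_slow_agent_discarded_after_twelve_sessions(self):
        agent = Agent(AgentParams(latency_median_s=1200.0), seed=1)
        gate, sessions = pretraining_gate(agent, load_preset("exp1_auto"))
        assert not gate.passed
        assert gate.sessions == 12
        assert all(r <= 2 for r in gate.rewards)

    def test_manual_gate_requires_all_twelve_approaches(self):
        ok = Agent(AgentParams(approach_rate=1.0), seed=1)
        gate, _ = pretraining_gate(ok, load_preset("exp1_manual"))
        assert gate.passed
        shy = Agent(AgentParams(approach_rate=0.3), seed=1)
        gate, _ = pretraining_gate(shy, load_preset("exp1_manual"))
        assert not gate.passed

    def test_barrier_gate_runs_two_stages(self):
        agent = Agent(AgentParams(), seed=2)
        gate, sessions = pretraining_gate(agent, load_preset("exp2"))
        assert gate.passed
        assert "barrier" in gate.detail

    def test_ramp_day_adds_four_graded_sessions(self):
        agent = Agent(AgentParams(), seed=3)
        cfg = load_preset("exp4B")
        gate, sessions = pretraining_gate(agent, cfg)
        assert gate.passed
        ramp = sessions[-4:]
        durations = [s.duration_s for s in ramp]
        # sessions of 15/30/45/60 minutes, each nearly filled
        for d, cap in zip(durations, (900, 1800, 2700, 3600)):
            assert d <= cap
        assert durations == sorted(durations)
        assert len(gate.rewards) == gate.sessions


class TestConfigValidation:
    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(mode="hybrid")

    def test_nonpositive_caps_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(daily_reinforcement_cap=0)

    def test_max_days_defaults(self):
        cfg = load_preset("exp1_auto")
        assert cfg.max_days_for("3v12") == 12
        assert cfg.max_days_for("2v3") == 10
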