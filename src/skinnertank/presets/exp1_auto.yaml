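# Benchmark arm: the baseline automated Skinner-tank procedure.
# 60-min daily sessions, 80 reinforcements/day cap, second session when
# the first yields < 40, 10-s correction-trial interval.
name: exp1_auto
mode: automated
chamber_variant: B
position_scheme: fixed
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
session_minutes: 60
pretraining_session_minutes: 30
intersession_minutes: 120
daily_reinforcement_cap: 80
low_yield_threshold: 40
correction_interval_s: 10
context_load: 1.0
pretraining: {type: auto, reward_target: 30, max_sessions: 12}
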