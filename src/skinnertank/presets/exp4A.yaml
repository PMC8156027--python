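# Residency: the subject lives in the conditioning chamber (built inside
# its home tank); standard 60-min/80-trial daily schedule.
name: exp4A
mode: automated
chamber_variant: E
position_scheme: varied18
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
session_minutes: 60
correction_interval_s: 10
resident: true
context_load: 0.55
pretraining: {type: auto, reward_target: 30, max_sessions: 12}
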