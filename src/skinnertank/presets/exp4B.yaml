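# Residency with spaced trials: 8-h daily sessions, the interval between
# an error and its correction trial raised from 10 s to 10 min, and a
# habituation ramp day (15/30/45/60-min sessions) added to pre-training.
name: exp4B
mode: automated
chamber_variant: E
position_scheme: varied18
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
session_minutes: 480
correction_interval_s: 600
resident: true
context_load: 0.55
pretraining: {type: ramp, reward_target: 30, max_sessions: 12}
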