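# Partition removal, stimuli over 18 rotated positions varying horizontal
# and vertical placement and inter-stimulus distance.
name: exp3B
mode: automated
chamber_variant: D
position_scheme: varied18
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
session_minutes: 60
correction_interval_s: 10
context_load: 0.98
pretraining: {type: auto, reward_target: 30, max_sessions: 12}
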