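# Decision-time elongation: larger chamber (start->choice 11.5 cm) and a
# transparent barrier the fish must detour before entering a choice area.
name: exp2
mode: automated
chamber_variant: C
position_scheme: fixed
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
session_minutes: 60
correction_interval_s: 10
context_load: 1.0
pretraining: {type: barrier, reward_target: 30, max_sessions: 12,
              narrow_factor: 1.3, wide_factor: 1.8}
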