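# Reduced cognitive load: the subject first learns to operate the device
# on shape, color and size discriminations, then faces the numerical task;
# a second shape task probes late-phase motivation.
name: exp5
mode: automated
chamber_variant: B
position_scheme: fixed
ladder: [shape, color, size, 3v12, shape2]
max_days: {default: 10}
session_minutes: 60
correction_interval_s: 10
context_load: 0.58
pretraining: {type: auto, reward_target: 30, max_sessions: 12}
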