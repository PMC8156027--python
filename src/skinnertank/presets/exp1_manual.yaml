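# Benchmark arm: traditional manual conditioning in the hourglass tank.
# 12 trials/day (6 morning + 6 afternoon), 15-min inter-trial and 90-min
# inter-session intervals, no correction trials, stimuli on printed cards.
name: exp1_manual
mode: manual
chamber_variant: B        # unused in manual mode
position_scheme: fixed
ladder: [3v12, 2v3, 3v4, 4v5, 5v6]
max_days: {3v12: 12, default: 10}
trials_per_day: 12
intertrial_minutes: 15
intersession_minutes: 90
context_load: 0.0
pretraining: {type: manual}
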