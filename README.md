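# skinnertank

A desk-scale simulator and analysis toolkit for automated operant
conditioning of small fish on numerosity discrimination tasks.

Automated Skinner-tank devices promise standardized, high-throughput
training of fish, but guppies (*Poecilia reticulata*) that sail through a
manual numerical-discrimination protocol perform near chance in the same
task inside an automated chamber. This package re-implements that whole
experimental pipeline in software so its pieces can be inspected, varied
and tested without a wet lab: controlled dot-array stimulus generation,
conditioning-chamber geometry and tracking, the trial/session protocol
engine for the manual benchmark and five automated variants (decision-time
elongation, partition removal, residency, spaced trials, reduced cognitive
load), simulated psychometric subjects, the statistical test battery, and
packaged per-subject performance tables from the benchmark study.

## The models at the core

**Stimulus control.** Dot arrays of numerosity n are controlled for the
continuous cues that co-vary with number: cumulative surface area
(Σπr², confined to ratio bands 0.76–0.85 / 0.86–0.95 / 0.96–1.05 across
each 24-pair set), convex hull, and density (n per hull area), with half
of each set hull-equated and half density-equated within 5%.

**Subject model.** Choice follows the standard approximate-number-system
psychometric function

    P(correct) = (1 − λ) · Φ( ln(nL/nS) / (√2 · w) ) + λ/2

with Weber fraction w and lapse rate λ, gated by a Rescorla–Wagner rule-
acquisition level q ← q + α(1 − q) on reward, and attenuated by a
cognitive-load context: engagement = q(1 − load_penalty · context_load).
Disengaged trials fall back to a side-biased coin.

**Learning criteria.** Primary: ≥ 75% correct pooled over two consecutive
days (18/24 manual trials). Secondary: ≥ 60% of all trials with an exact
two-sided binomial test vs chance (87/144 for 3 vs 12, 72/120 otherwise).

## Worked example

Simulate the benchmark contrast — the same agent population trained
manually and in the automated chamber on 3 vs 12
(`examples/04_manual_vs_automated.py`):

```text
exp1_manual: accuracy 79.55 ± 7.76 (n=11)
  outcomes {'primary': 11, 'secondary': 0, 'failed': 0}, trials to criterion 29.45 ± 6.27 (n=11)
  one-sample t vs 50%: t(10) = 12.63, p = 1.81e-07
exp1_auto: accuracy 50.79 ± 0.81 (n=8)
  outcomes {'primary': 0, 'secondary': 0, 'failed': 8}
  one-sample t vs 50%: t(7) = 2.73, p = 0.0291
```

Every simulated manual subject reaches the primary criterion within a few
dozen trials, while every automated subject performs hundreds of trials
near chance and fails — the qualitative signature of the benchmark study.
Recomputing the published group statistics from the packaged per-subject
tables (`examples/05_published_tables.py`) gives

```text
  manual_3v12_mean_trials                    55.636
  manual_3v12_mean_accuracy_pct              70.249
  manual_3v12_t_vs_chance                     9.606
  auto_3v12_mean_trials                     532.875
  auto_3v12_mean_accuracy_pct                51.545
  exp4_pooled_3v12_mean_accuracy_pct         59.881
  manual_vs_auto_t                            6.650
```

i.e. manually trained subjects needed on average 55.6 trials to criterion
at 70.2% accuracy, automated subjects stayed at 51.5% over 532.9 trials,
and the two arms differ at t(17) = 6.65; residency recovers intermediate
performance (59.9%).

The other examples build and verify a controlled stimulus set, track a
synthetic swim path through the chamber zones, and replay a full automated
session with correction trials; each prints what its numbers mean. The
same functionality is scriptable from the shell:

```sh
skinnertank stimuli --contrast 2v3 --seed 7 --out pairs.json
skinnertank simulate --preset exp1_auto --seed 11 --out run.jsonl
skinnertank analyze run.jsonl
skinnertank tables --fixture table1 --recompute
```

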