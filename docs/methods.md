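# Methods

`skinnertank` is a desk-scale re-implementation of an automated
operant-conditioning pipeline for small fish: it generates the controlled
numerosity stimuli, models the conditioning chambers, runs the full
trial/session protocols (one manual benchmark and five automated
variants), simulates subjects, and recomputes the study's statistics from
packaged per-subject tables. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
parts do and do not show.

## Stimulus generation

A stimulus is a set of black dots (centers + radii, continuous cm, origin
at the field's lower-left corner) on a white field: the 3 × 3 cm printed
card of the manual procedure or the 6 × 5 cm monitor window of the
automated chambers. Numerosity co-varies with continuous quantities, so a
discrimination set controls three of them:

* **Cumulative surface area.** Dot diameters span 0.75–0.95 cm and per-set
  diameters are jointly rescaled so the ratio of total dot area
  (smaller/larger set) falls in one of three bands — 0.76–0.85, 0.86–0.95,
  0.96–1.05 — with 8 of 24 pairs per band. The 3 vs 12 set (18 pairs) is
  exempt from the area bands and controlled for hull and density only.
* **Convex hull** and **density.** Half of each set equates the convex
  hull of the two arrays, half equates their density (numerosity per hull
  area). Density is defined on the convex hull of dot *centers*, the
  standard convention in numerical-cognition stimulus control; a 2-dot
  array has a degenerate center hull, so pairs whose smaller array has
  fewer than 3 dots (the 2 vs 3 contrast) are matched on the convex hull
  of the dot *disks* instead. `matching_metrics` reports which convention
  a pair uses, and `StimulusPair.verify()` re-checks every constraint from
  the raw geometry.

Matching tolerance is 5% relative — "equated" is not further quantified in
the protocol, and 5% is reliably achievable by stochastic search at every
numerosity used. Minimum edge-to-edge dot gap is 0.1 cm.

**Generation algorithm.** Radii are drawn first (for banded pairs, the
smaller set's radii are iteratively rescaled and clipped until their disk
area hits a target ratio sampled inside the band). The larger array is
placed by random sequential placement inside a centered sub-box whose
scale adapts across attempts (compact for hull matching, spread for
density matching), with a jittered-grid + pairwise-repulsion fallback for
dense configurations. The smaller array is then constructed to a target
hull area (the larger's hull, or numerosity-scaled for density matching)
by repeated centroid scaling with boundary clamping and repulsion repair.
Each candidate pair is verified from scratch; failures restart, and after
a configurable attempt budget a `ConstraintError` names the violated
constraint.

**Packing relaxation.** Twelve 0.75–0.95 cm dots cannot fit a 3 × 3 cm
card without overlap. When the nominal dot-area fraction of a field
exceeds 0.4, diameters rescale uniformly to reach 0.4, and the relaxation
applies *pair-wide* (both arrays share the scale) so that cross-array
equating stays meaningful. Even relaxed, 12 dots on the manual card cannot
contract their center hull below the largest triangle 3 dots can span
there, so hull-matched 3 vs 12 pairs are infeasible on the card; the
generator detects this analytically and fails fast with a named error.
Default set generation therefore uses the 6 × 5 cm display window, where
every constraint is satisfiable.

**Positioning.** The `fixed` scheme presents the pair centrally (left/
right mirroring only). The `varied18` scheme enumerates 18 placements — 3
horizontal offsets × 3 vertical offsets × 2 inter-stimulus separations —
presented in rotation (each used exactly twice per 36 trials). The
published protocol references the 18 positions to earlier work without
printing the layout; this grid is the package's documented default.

## Chamber model

Each automated chamber is a rectangle divided into start area, corridor,
V-shaped decision funnel, and two choice areas. Published dimensions fix
zone sizes but not vertex coordinates; the funnel is realized as a
trapezoid widening from the corridor mouth to the full width, and every
variant's polygon set is validated against the declared start-exit →
choice-entrance distance (B: 6 cm, C: 11.5, D: 17.5, E: 18.5; ±0.1 cm).
Variant E's published zone depths sum to 33 cm inside a 32 cm chamber;
the start area is modeled 9 cm deep (not 10) to honour both the chamber
length and the declared distance. Variant D has no corridor zone (its
partitions are removed).

Zone classification is half-open: a point on a shared edge belongs to the
zone later in the order start < corridor < decision < choice. Traces are
debounced: a zone entry is committed only after `min_dwell` (default
0.2 s) of consecutive samples in the new zone, suppressing boundary
jitter. The below-tank camera is emulated by rendering the fish as a dark
0.9 × 0.35 cm ellipse on a light background (optionally with additive
Gaussian noise) and recovering position by darkness-weighted centroid,
accurate to well under 0.2 cm at 5 px/cm.

## Subject model

No trial-by-trial data from live subjects are published, so the engine is
exercised with explicitly synthetic agents (no biological validity is
claimed beyond the ratio effect they encode):

* **Psychometric core** — log-Gaussian magnitude representation:
  P(correct | engaged) = (1 − λ) Φ(ln(nL/nS) / (√2 · w)) + λ/2 with Weber
  fraction `w` (default 0.30, the order of magnitude typical of trained
  guppies) and lapse rate λ (default 0.05). Feature (shape/color/size)
  tasks use a fixed discriminability d′ = 2.5, reflecting that their
  stimuli do not change across trials.
* **Rule acquisition** — a Rescorla–Wagner-style level q ∈ [0, 1]
  (probability of applying the "approach the larger set" rule), updated
  q ← q + α(1 − q) on rewarded choices only (α default 0.08, q₀ = 0.3),
  producing multi-day learning curves at realistic reward densities.
* **Cognitive load** — engagement = q · (1 − load_penalty · context_load).
  Each preset carries a context load (manual 0.0; baseline automated and
  barrier variants 1.0; partitions-removed 0.98; resident variants 0.55;
  after device pre-training 0.58). These values are free configuration
  chosen once so that the simulated cohorts reproduce the *qualitative*
  pattern of the study — manual subjects pass easily, baseline automated
  subjects hover near chance, residency and reduced load recover
  intermediate performance. They are not fitted quantities.
* **Latency** — lognormal decision latency (median 40 s at the baseline
  chamber, σ = 0.4) scaled by the chamber's start→choice distance
  (manual ≈ 22 cm ⇒ roughly three times the baseline choice time).
  Pre-training shuttle cycles involve no stimulus evaluation and run at
  the base latency, with a slowdown factor only for the barrier detour.
* Degenerate reference agents (chance, always-left, perfect) exist for
  engine testing, and `fit_weber` recovers `w` (and λ) by maximum
  likelihood from per-contrast choice counts.

## Protocol engine

Discrete-event simulation with a per-day clock in seconds. Manual mode:
12 analyzable trials/day (6 + 6, sides counterbalanced 6/6 with no run of
three), reward iff the first approach is to the larger set, no correction
trials. Automated mode: sessions end at 60 min (8 h in the spaced
variant) or at the daily cap of 80 reinforcements; a second session (2 h
later) occurs iff the first yielded < 40, capped at the daily remainder;
errors blank the screen and trigger correction trials — same pair, same
side, after 10 s (10 min in the spaced variant) — repeated until correct,
excluded from all accuracy tallies, with a safeguard cap (default 30) and
a flagged record for agents that would never choose the correct side.
Side schedules are uniform with runs of three forbidden (implemented by
redraw; over length-3 windows exactly the 6 triple-free sequences have
positive probability, the two double-then-forced ones at twice the rate
of the rest).

Learning criteria: primary — pooled accuracy over two consecutive days
≥ 75% (per-day mode available as a configuration switch; pooling matches
the 18/24 arithmetic of the manual protocol); secondary — ≥ 60% of all
trials of the contrast and an exact two-sided binomial test vs 0.5 at
α = 0.05, i.e. 87/144 for 3 vs 12 and 72/120 for the 10-day contrasts.
Day caps are 12 days for 3 vs 12 and 10 days thereafter in both modes.
The ladder runs 3v12 → 2v3 → 3v4 → 4v5 → 5v6 (or shape → color → size →
3v12 → second shape in the reduced-load preset), advances only on
criterion, and stops at the first failure.

Pre-training gates: manual — approach the card on all 12 presentations of
day 2; automated — ≥ 30 rewards summed over a same-day pair of 30-min
sessions (the published wording is ambiguous between summed and per-
session; summed is the default, and the target is configurable), within
12 sessions; the barrier variant first requires one ≥ 30-reward session
with the narrow barrier; the spaced variant appends a 15/30/45/60-min
habituation ramp day.

Reproducibility: one master seed splits (numpy `SeedSequence`) into
independent streams for side scheduling, stimulus sampling, and agent
behavior, making runs bit-reproducible and side schedules comparable
across agents.

## Statistics

Exact two-sided binomial test by the sum-of-small-probabilities
definition (all outcomes whose point probability does not exceed the
observed one, with a 1e-7 relative slack against floating-point ties) —
this is pinned by the published example 32/48 → p = 0.029 and verified
exhaustively against an independent enumeration for all n ≤ 200.
One-sample and pooled two-sample Student t-tests (Welch by flag),
Cohen's kappa with the standard large-sample null-variance z-test, and
the Mann–Whitney U test (exact enumeration for small untied samples,
tie-corrected normal approximation otherwise; ties take midranks).
Summaries are mean ± sample sd (n − 1; sd = 0 by convention for a single
observation). A fixed-effects logistic regression of correctness on
session index is provided as a descriptive substitute for mixed-model
learning-curve analyses; it ignores between-subject variation and is
clearly labeled non-equivalent to a GLMM, whose χ² values are out of
scope.

## Packaged tables

Seven CSV fixtures transcribe the published per-subject records:
correct/total counts, the printed session-mean accuracy percentage ± sd,
and the printed binomial p. Printed percentages and pooled fractions
differ by construction (variable session lengths; up to ~11 points in the
residency tables), so group means and t-tests use the printed percentage
column — the quantity the published group statistics were computed from —
while per-subject binomial tests use the counts. One internal
inconsistency is preserved as printed (manual table, subject 11, 5 vs 6:
"52.50%; 61/120" although 61/120 = 50.83%); the printed percentages
reproduce the published t = 3.464 exactly when the unrounded fractions
are used and within 0.007 from the 2-dp entries.

## What the synthetic parts show — and do not

Passing tests demonstrate that the *protocol machinery* is faithful
(caps, schedules, corrections, criteria, reproducibility) and that the
statistics reproduce the published values from the published tables. The
agent simulation reproduces qualitative signatures only: the numerical
ratio effect, near-chance automated baseline performance, and the
residency/reduced-load recovery. It does not model real fish (stress,
motivation drift, session-to-session variability far exceeding binomial
noise — visible in the tables' large printed sds — or the late-phase
motivation loss that truncated the reduced-load experiment).

One statistical property is knowingly unattainable and its check is left
failing rather than weakened: a pure chance agent fails the easiest
manual contrast with probability 0.8916 (exact enumeration over
Bin(12, 0.5) day scores under the two-consecutive-day pooled 18/24
primary rule and the 87/144 secondary rule), so no simulation can fail in
"more than 95%" of seeds; observed rates over 200 seeds sit near 89–91%.

## Problem sizes

Default simulations are single-subject runs of at most 12 days per
contrast (≈ 500–900 analyzable automated trials); cohort examples use
8–11 subjects; seeded property checks use 10,000 choices per contrast for
the ratio effect, 20 seeds × 2,000 choices for Weber recovery, and 50–200
seeds for pass/fail rates. The full test suite completes in well under a
minute on one CPU.
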