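"""Simulate the manual-vs-automated benchmark contrast on 3 vs 12.

The same agent population is trained under the manual protocol (12
trials/day, no device overhead) and the baseline automated protocol
(hundreds of trials/day, high cognitive-load context). The manual cohort
should reach criterion quickly; the automated cohort should hover near
chance — the qualitative signature of the benchmark study.
"""

import dataclasses

from skinnertank.agents import AgentParams
from skinnertank.engine import run_ladder
from skinnertank.io import load_preset
from skinnertank.stats import summarize_cohort

for preset, n_subjects in (("exp1_manual", 11), ("exp1_auto", 8)):
    cfg = dataclasses.replace(load_preset(preset), ladder=("3v12",))
    runs = [run_ladder(AgentParams(), cfg, seed=1000 + i, skip_gate=True,
                       subject_id=f"S{i + 1}")
            for i in range(n_subjects)]
    s = summarize_cohort(runs, "3v12")
    print(f"{preset}: accuracy {s['accuracy']}")
    print(f"  outcomes {s['outcomes']}", end="")
    if "trials_to_criterion" in s:
        print(f", trials to criterion {s['trials_to_criterion']}", end="")
    print()
    if "t_vs_chance" in s:
        t = s["t_vs_chance"]
        print(f"  one-sample t vs 50%: t({t.df}) = {t.statistic:.2f}, "
          f"p = {t.pvalue:.3g}")
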