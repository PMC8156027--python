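"""Run one simulated subject through the automated 3 vs 12 protocol.

Training sessions last 60 minutes or 80 reinforcements, whichever comes
first; a second daily session happens only after a low-yield first one.
Errors trigger correction trials (same pair, same side) that are logged
but excluded from accuracy.
"""

import dataclasses

from skinnertank.agents import AgentParams
from skinnertank.engine import run_ladder
from skinnertank.io import load_preset
from skinnertank.stats import summarize_run

cfg = dataclasses.replace(load_preset("exp1_auto"), ladder=("3v12",))
run = run_ladder(AgentParams(), cfg, seed=11)

print(f"pre-training gate: passed={run.gate.passed}, "
      f"rewards per session {run.gate.rewards}")
for s in run.sessions:
    if s.phase != "training":
        continue
    k, n = s.tally()
    n_corr = sum(t.is_correction for t in s.trials)
    print(f"day {s.day:2d} session {s.index}: {k:3d}/{n:3d} correct "
          f"({100 * k / max(n, 1):5.1f}%), {n_corr:3d} correction trials, "
          f"{s.reinforcements} reinforcements")

entry = summarize_run(run)["3v12"]
crit = entry["criterion"]
print(f"\noverall: {entry['correct']}/{entry['total']} "
      f"({entry['accuracy_pct']:.2f}%), binomial p = "
      f"{entry['binomial'].pvalue:.3g}, outcome: {crit.outcome}")
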