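"""Recompute the benchmark study's group statistics from the packaged
per-subject tables.

The fixtures transcribe the published tables (correct/total counts and
printed session-mean accuracy percentages). The report below recomputes
the headline numbers — mean trials to criterion, group accuracies, t
tests against chance, and the manual-vs-automated comparison — through
the package's stats layer.
"""

from skinnertank.tables import benchmark_report, fixture_report_text

print(fixture_report_text("table1", recompute=True))
print()
print(fixture_report_text("table2", recompute=True))

print("\nheadline quantities:")
for key, value in benchmark_report().items():
    print(f"  {key:40s} {value:8.3f}")
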