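"""Packaged per-subject performance tables and their recomputation.

The seven fixture tables transcribe the published per-subject records of
the benchmark study: for every subject and task, the number of correct
choices, the number of analyzable trials, the printed accuracy percentage
(mean over daily sessions) with its sd, and the printed binomial p-value.

Two accuracy notions coexist in these tables. The *printed* percentage is
the mean of per-session accuracies, while correct/total gives the pooled
proportion; for the long automated runs the two differ because session
lengths vary. Group means and t-tests below therefore use the printed
percentage column, which is what the published group statistics were
computed from; the pooled fraction feeds the per-subject binomial tests.

One internal inconsistency is preserved as printed: the manual table's
subject 11 at 5 vs 6 prints "52.50%; 61/120" although 61/120 = 50.83%.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import TestResult, binom_two_sided, one_sample_t, summary, two_sample_t

__all__ = [
    "FIXTURES",
    "load_fixture",
    "recompute_binomials",
    "task_accuracy",
    "task_summary",
    "mean_trials",
    "benchmark_report",
    "fixture_report_text",
]

FIXTURES = ("table1", "table2", "table3", "table4", "table5", "table6",
            "table7")

# experiment tag per fixture (table1 = manual arm, table2 = automated arm)
_EXPERIMENT = {"table1": "exp1_manual", "table2": "exp1_auto",
               "table3": "exp2", "table4": "exp3", "table5": "exp4A",
               "table6": "exp4B", "table7": "exp5"}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table fixture and check its internal consistency."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; one of {FIXTURES}")
    with resources.files("skinnertank.fixtures").joinpath(f"{name}.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"p_text": str})
    df["condition"] = df["condition"].fillna("")
    if (df["correct"] > df["total"]).any() or (df["correct"] < 0).any():
        raise ValueError(f"{name}: correct counts outside [0, total]")
    if ((df["accuracy_pct"] < 0) | (df["accuracy_pct"] > 100)).any():
        raise ValueError(f"{name}: percentage outside [0, 100]")
    df.insert(0, "experiment", _EXPERIMENT[name])
    return df


def recompute_binomials(df: pd.DataFrame, p0: float = 0.5) -> pd.DataFrame:
    """Add pooled accuracy and an exact binomial test recomputed from the
    correct/total counts of every row."""
    out = df.copy()
    out["pooled_pct"] = 100.0 * out["correct"] / out["total"]
    out["binom_p"] = [binom_two_sided(k, n, p0).pvalue
                      for k, n in zip(out["correct"], out["total"])]
    return out


def task_accuracy(df: pd.DataFrame, task: str,
                  column: str = "accuracy_pct") -> np.ndarray:
    sel = df.loc[df["task"] == task, column].to_numpy(dtype=float)
    if sel.size == 0:
        raise ValueError(f"no rows for task {task!r}")
    return sel


def task_summary(df: pd.DataFrame, task: str) -> dict:
    """Across-subject accuracy summary and t-test vs chance for one task."""
    acc = task_accuracy(df, task)
    res: dict = {"n": int(acc.size), "accuracy": summary(acc)}
    if acc.size >= 2 and acc.std(ddof=1) > 0:
        res["t_vs_chance"] = one_sample_t(acc, 50.0)
    return res


def mean_trials(df: pd.DataFrame, task: str) -> float:
    """Mean number of analyzable trials performed on a task (for subjects
    that reached criterion this equals trials to criterion)."""
    return float(task_accuracy(df, task, column="total").mean())


def benchmark_report() -> dict:
    """Recompute the headline group statistics of the benchmark study from
    the packaged fixtures.

    Returns a flat dict of scalars: group accuracy means (percent), mean
    trial counts, one-sample t statistics vs 50%, the pooled manual-vs-
    automated two-sample t, and the pooled means of the partition-removal
    and residency experiments.
    """
    t1 = load_fixture("table1")
    t2 = load_fixture("table2")
    t4 = load_fixture("table4")
    t56 = pd.concat([load_fixture("table5"), load_fixture("table6")])
    manual_acc = task_accuracy(t1, "3v12")
    auto_acc = task_accuracy(t2, "3v12")
    report = {
        "manual_3v12_mean_trials": mean_trials(t1, "3v12"),
        "manual_3v12_mean_accuracy_pct": float(manual_acc.mean()),
        "manual_2v3_mean_accuracy_pct": float(task_accuracy(t1, "2v3").mean()),
        "manual_3v4_mean_accuracy_pct": float(task_accuracy(t1, "3v4").mean()),
        "manual_3v12_t_vs_chance": one_sample_t(manual_acc, 50.0).statistic,
        "manual_5v6_t_vs_chance": one_sample_t(
            task_accuracy(t1, "5v6"), 50.0).statistic,
        "auto_3v12_mean_trials": mean_trials(t2, "3v12"),
        "auto_3v12_mean_accuracy_pct": float(auto_acc.mean()),
        "exp3_3v12_mean_accuracy_pct": float(task_accuracy(t4, "3v12").mean()),
        "exp4_pooled_3v12_mean_accuracy_pct": float(
            task_accuracy(t56, "3v12").mean()),
        "manual_vs_auto_t": two_sample_t(manual_acc, auto_acc,
                                         pooled=True).statistic,
    }
    return report


def fixture_report_text(name: str, recompute: bool = False) -> str:
    """Human-readable per-task report for one fixture table."""
    df = load_fixture(name)
    if recompute:
        df = recompute_binomials(df)
    lines = [f"{name} ({_EXPERIMENT[name]}): {df['subject'].nunique()} subjects"]
    for task in df["task"].unique():
        s = task_summary(df, task)
        line = f"  {task:12s} accuracy {s['accuracy']}"
        if "t_vs_chance" in s:
            t = s["t_vs_chance"]
            line += f"; t({t.df}) = {t.statistic:.3f}, p = {t.pvalue:.3g}"
        line += f"; mean trials {mean_trials(df, task):.2f}"
        lines.append(line)
    if recompute:
        n_sig = int((df["binom_p"] < 0.05).sum())
        lines.append(f"  per-subject binomial tests: {n_sig}/{len(df)} "
                     "rows significant at 0.05")
    return "\n".join(lines)
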