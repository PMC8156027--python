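"""Statistical test battery and summary layer for behavioral session data.

Implements the tests used throughout the analysis of operant-conditioning
sessions: the exact two-sided binomial test (sum-of-small-probabilities
definition, matching the default of the common statistical environments),
one-sample and pooled two-sample t-tests, Cohen's kappa with an asymptotic
significance test, the Mann-Whitney U test, and mean +/- sd summaries of
per-subject accuracy and trials/days to criterion.

Every test returns a :class:`TestResult` carrying the statistic, degrees of
freedom where applicable, and a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "SummaryStats",
    "binom_two_sided",
    "one_sample_t",
    "two_sample_t",
    "cohen_kappa",
    "mann_whitney_u",
    "summary",
    "summarize_run",
    "summarize_cohort",
    "session_trend",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    method : short tag identifying the test ("binomial", "t-one-sample", ...).
    statistic : the test statistic (k for the binomial test).
    df : degrees of freedom, or ``None`` where the test has none.
    pvalue : two-sided p-value in [0, 1].
    """

    method: str
    statistic: float
    df: float | None
    pvalue: float
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- sample standard deviation summary (n-1 denominator).

    For a single observation the sd is reported as 0.0 by convention.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary requires at least one observation")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def __str__(self) -> str:  # "55.64 +/- 35.30" style
        return f"{self.mean:.2f} ± {self.sd:.2f} (n={self.n})"


# Relative slack when comparing point probabilities in the exact binomial
# test; guards against floating-point ties the same way R's binom.test does.
_BINOM_RELERR = 1.0 + 1e-7


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test of k successes in n trials vs p0.

    The two-sided p-value is the total probability of all outcomes whose
    point probability does not exceed that of the observed ``k``
    (the sum-of-small-probabilities method).
    """
    k = int(k)
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    p = float(pmf[pmf <= pmf[k] * _BINOM_RELERR].sum())
    return TestResult("binomial", float(k), None, min(p, 1.0),
                      extra={"n": n, "p0": p0, "estimate": k / n})


def one_sample_t(values: Sequence[float], mu: float) -> TestResult:
    """One-sample Student t-test of the mean of ``values`` against ``mu``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one-sample t-test needs >= 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one-sample t-test undefined for constant input")
    n = x.size
    t = (x.mean() - mu) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult("t-one-sample", float(t), n - 1, float(p))


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 pooled: bool = True) -> TestResult:
    """Two-sample t-test; pooled-variance Student by default, Welch by flag."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("two-sample t-test undefined for two constant groups")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = a.size + b.size - 2 if pooled else float(res.df)
    method = "t-two-sample-pooled" if pooled else "t-two-sample-welch"
    return TestResult(method, float(res.statistic), df, float(res.pvalue))


def cohen_kappa(ratings1: Sequence, ratings2: Sequence) -> TestResult:
    """Cohen's kappa between two raters with an asymptotic z-test vs kappa=0.

    kappa = (po - pe) / (1 - pe) where po is observed agreement and pe the
    agreement expected from the marginal rating frequencies. The p-value uses
    the standard large-sample null variance
    var0 = [pe + pe^2 - sum_i pi.p.i(pi. + p.i)] / (N (1 - pe)^2).
    """
    r1 = np.asarray(ratings1)
    r2 = np.asarray(ratings2)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D sequences")
    n = r1.size
    if n == 0:
        raise ValueError("empty ratings")
    cats = np.unique(np.concatenate([r1, r2]))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(r1, r2):
        table[idx[a], idx[b]] += 1
    table /= n
    po = np.trace(table)
    prow = table.sum(axis=1)
    pcol = table.sum(axis=0)
    pe = float(prow @ pcol)
    if pe == 1.0:  # a single observed category: agreement is uninformative
        raise ValueError("kappa undefined: only one rating category observed")
    kappa = (po - pe) / (1.0 - pe)
    var0 = (pe + pe**2 - float(np.sum(prow * pcol * (prow + pcol)))) \
        / (n * (1.0 - pe) ** 2)
    if var0 <= 0:
        p = 0.0 if kappa != 0 else 1.0
    else:
        z = kappa / np.sqrt(var0)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("cohen-kappa", float(kappa), None, p,
                      extra={"po": float(po), "pe": pe, "n": n})


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Mann-Whitney U test; exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise. Ties take midranks."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 observation")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size + b.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann-whitney-u", float(res.statistic), None,
                      float(res.pvalue), extra={"mode": method})


def summary(values: Sequence[float]) -> SummaryStats:
    """Mean +/- sample sd of ``values`` (sd = 0 for a single observation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(int(x.size), float(x.mean()), sd)


def summarize_run(run) -> dict:
    """Per-task summary of one subject run (or of a fixture table).

    For a simulated run (an object with ``results`` and ``sessions``):
    per task, pooled correct/total over analyzable trials, accuracy
    percentage, an exact binomial test vs chance, and the criterion
    outcome. For a pandas DataFrame fixture: per task, the across-subject
    accuracy summary and the mean trial count.
    """
    if hasattr(run, "columns"):  # fixture table
        out = {}
        for task in run["task"].unique():
            sub = run[run["task"] == task]
            acc = sub["accuracy_pct"].to_numpy(dtype=float)
            out[task] = {"accuracy": summary(acc),
                         "mean_trials": float(sub["total"].mean())}
        return out
    if not hasattr(run, "results"):
        raise TypeError("expected a SubjectRun or a fixture DataFrame")
    out = {}
    for task, result in run.results.items():
        k = n = 0
        for sess in run.sessions:
            if sess.task == task and sess.phase == "training":
                dk, dn = sess.tally()
                k += dk
                n += dn
        entry = {"correct": k, "total": n,
                 "accuracy_pct": 100.0 * k / n if n else float("nan"),
                 "criterion": result}
        if n:
            entry["binomial"] = binom_two_sided(k, n, 0.5)
        out[task] = entry
    return out


def summarize_cohort(runs, task: str) -> dict:
    """Across-subject summary for one task over several subject runs:
    accuracy mean +/- sd (percent, pooled per subject), mean trials and
    days among criterion reachers, outcome counts, and a t-test vs 50%."""
    accs, trials, days = [], [], []
    outcomes = {"primary": 0, "secondary": 0, "failed": 0}
    for run in runs:
        per_task = summarize_run(run)
        if task not in per_task:
            continue
        entry = per_task[task]
        if entry["total"]:
            accs.append(entry["accuracy_pct"])
        result = entry["criterion"]
        outcomes[result.outcome] += 1
        if result.outcome != "failed":
            trials.append(result.trials_to_criterion)
            days.append(result.days_to_criterion)
    if not accs:
        raise ValueError(f"no runs performed task {task!r}")
    out: dict = {"task": task, "accuracy": summary(accs),
                 "outcomes": outcomes}
    if trials:
        out["trials_to_criterion"] = summary(trials)
        out["days_to_criterion"] = summary(days)
    if len(accs) >= 2 and np.std(accs, ddof=1) > 0:
        out["t_vs_chance"] = one_sample_t(accs, 50.0)
    return out


def session_trend(correct: Sequence[int], total: Sequence[int]) -> TestResult:
    """Descriptive fixed-effects logistic regression of accuracy on session.

    Fits P(correct) ~ logit^-1(b0 + b1 * session_index) by a binomial GLM and
    reports the Wald z test on the slope. This is a descriptive,
    fixed-effects substitute for a mixed model: it ignores between-subject
    variation and is NOT equivalent to a GLMM with random subject effects.
    """
    import statsmodels.api as sm

    k = np.asarray(correct, dtype=float)
    n = np.asarray(total, dtype=float)
    if k.shape != n.shape or k.ndim != 1 or k.size < 2:
        raise ValueError("need per-session (correct, total) pairs, >= 2 sessions")
    sessions = np.arange(1, k.size + 1, dtype=float)
    X = sm.add_constant(sessions)
    fit = sm.GLM(np.column_stack([k, n - k]), X,
                 family=sm.families.Binomial()).fit()
    z = float(fit.tvalues[1])
    return TestResult("logistic-session-trend", z, None, float(fit.pvalues[1]),
                      extra={"slope": float(fit.params[1])})
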