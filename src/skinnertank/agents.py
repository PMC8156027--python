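"""Simulated subjects: psychometric choice, rule acquisition, and latency.

No trial-by-trial data from live fish are published, so the protocol
engine is exercised with synthetic agents. The agent model is the standard
approximate-number-system account: numerosities are represented as noisy
log-magnitudes with Weber fraction ``w``, so the probability of choosing
the larger of nS < nL items (ignoring lapses) is

    Phi( ln(nL/nS) / (sqrt(2) * w) )

where Phi is the standard normal CDF and the sqrt(2) combines the noise of
the two independent estimates. A lapse rate ``lapse`` mixes in stimulus-
independent responding, bounding asymptotic accuracy at 1 - lapse/2.

On top of the psychometric core sits a Rescorla-Wagner-style acquisition
state q in [0, 1]: the probability that the subject applies the learned
"approach the larger numerosity" rule at all. Rewarded choices update
q <- q + alpha (1 - q); unrewarded choices leave q unchanged (asymmetric
acquisition). When the rule is not applied, the agent chooses by a
side-biased coin with P(left) = (1 + beta) / 2.

A per-preset cognitive-load context multiplies effective engagement:
engagement = q * (1 - load_penalty * context_load). This single knob lets
the suite mimic, qualitatively, why the same subjects discriminate well in
a manual tank (load 0) and poorly in an automated chamber (load near 1),
and why residency or device pre-training improves automated performance.
The load values attached to presets are free configuration, not measured
quantities.

All agent machinery is an explicitly synthetic stand-in for live subjects;
it claims no biological validity beyond the ratio effect it encodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "AgentParams",
    "AgentState",
    "Agent",
    "p_correct_numerosity",
    "p_correct_feature",
    "acquire_rule",
    "default_agent",
    "chance_agent",
    "always_left_agent",
    "perfect_agent",
    "fit_weber",
]


@dataclass(frozen=True)
class AgentParams:
    """Psychometric and learning parameters of a simulated subject.

    weber : Weber fraction of the magnitude representation (> 0).
    lapse : stimulus-independent response probability, in [0, 1].
    side_bias : beta in [-1, 1]; P(left) = (1 + beta)/2 when guessing.
    acquisition : Rescorla-Wagner rate alpha in [0, 1].
    load_penalty : in [0, 1]; engagement multiplier under cognitive load.
    q0 : initial rule-acquisition level.
    feature_dprime : discriminability of the shape/color/size warm-up
        stimuli (their identity does not change across trials, so they are
        easier than numerosity; expressed as a d' entering Phi(d'/sqrt 2)).
    latency_median_s / latency_sigma : lognormal decision-latency model,
        scaled by the chamber's start->choice distance.
    approach_rate : probability of approaching a presented card during
        manual pre-training.
    """

    weber: float = 0.30
    lapse: float = 0.05
    side_bias: float = 0.0
    acquisition: float = 0.08
    load_penalty: float = 0.97
    q0: float = 0.30
    feature_dprime: float = 2.5
    latency_median_s: float = 40.0
    latency_sigma: float = 0.40
    approach_rate: float = 0.98

    def __post_init__(self):
        if self.weber <= 0:
            raise ValueError("weber must be positive")
        for name, lo, hi in (("lapse", 0, 1), ("side_bias", -1, 1),
                             ("acquisition", 0, 1), ("load_penalty", 0, 1),
                             ("q0", 0, 1), ("approach_rate", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class AgentState:
    q: float
    rng: np.random.Generator
    left_choices: int = 0
    right_choices: int = 0

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q outside [0, 1]")


def p_correct_numerosity(n_small: int, n_large: int, weber: float,
                         lapse: float = 0.0) -> float:
    """Probability of choosing the larger set under the log-Gaussian model."""
    if n_small >= n_large:
        raise ValueError("requires n_small < n_large")
    if weber <= 0:
        raise ValueError("weber must be positive")
    p = norm.cdf(math.log(n_large / n_small) / (math.sqrt(2.0) * weber))
    return (1.0 - lapse) * float(p) + lapse / 2.0


def p_correct_feature(dprime: float, lapse: float = 0.0) -> float:
    """Probability of choosing the positive feature stimulus."""
    p = norm.cdf(dprime / math.sqrt(2.0))
    return (1.0 - lapse) * float(p) + lapse / 2.0


def acquire_rule(q: float, alpha: float, rewarded: bool) -> float:
    """Asymmetric Rescorla-Wagner update of the rule-acquisition level."""
    if not 0.0 <= q <= 1.0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("q and alpha must lie in [0, 1]")
    return q + alpha * (1.0 - q) if rewarded else q


class Agent:
    """A stateful simulated subject bound to one RNG stream."""

    def __init__(self, params: AgentParams, seed=None):
        self.params = params
        self.state = AgentState(q=params.q0, rng=np.random.default_rng(seed))

    def reset(self, seed=None) -> None:
        self.state = AgentState(q=self.params.q0,
                                rng=np.random.default_rng(seed))

    # -- behavior ----------------------------------------------------------

    def p_rule_correct(self, task) -> float:
        """Accuracy of the rule pathway for a task: a numerical contrast
        (n_small, n_large) or a feature-task name."""
        if isinstance(task, tuple):
            return p_correct_numerosity(task[0], task[1], self.params.weber,
                                        self.params.lapse)
        return p_correct_feature(self.params.feature_dprime, self.params.lapse)

    def choose(self, task, correct_side: str, context_load: float = 0.0) -> str:
        """Return 'left' or 'right' for one trial.

        With probability q * (1 - load_penalty * context_load) the agent
        engages the learned rule and is correct with the psychometric
        probability; otherwise it answers by a side-biased coin.
        """
        st, p = self.state, self.params
        engagement = st.q * (1.0 - p.load_penalty * float(context_load))
        if st.rng.random() < engagement:
            correct = st.rng.random() < self.p_rule_correct(task)
            side = correct_side if correct else \
                ("left" if correct_side == "right" else "right")
        else:
            side = "left" if st.rng.random() < (1.0 + p.side_bias) / 2.0 else "right"
        if side == "left":
            st.left_choices += 1
        else:
            st.right_choices += 1
        return side

    def update(self, rewarded: bool) -> None:
        self.state.q = acquire_rule(self.state.q, self.params.acquisition,
                                    rewarded)

    def latency(self, distance_scale: float = 1.0) -> float:
        """Decision latency in seconds (start-area exit to choice entry and
        return), lognormal with the median scaled by chamber distance."""
        mu = math.log(self.params.latency_median_s * distance_scale)
        return float(self.state.rng.lognormal(mu, self.params.latency_sigma))

    def approaches_card(self) -> bool:
        return bool(self.state.rng.random() < self.params.approach_rate)


# -- reference agents -------------------------------------------------------

def default_agent(**overrides) -> AgentParams:
    return replace(AgentParams(), **overrides) if overrides else AgentParams()


def chance_agent() -> AgentParams:
    """Never engages the rule: responds by a fair coin."""
    return AgentParams(q0=0.0, acquisition=0.0, side_bias=0.0)


def always_left_agent() -> AgentParams:
    """Degenerate fully side-biased agent."""
    return AgentParams(q0=0.0, acquisition=0.0, side_bias=1.0)


def perfect_agent() -> AgentParams:
    """Noiseless, lapse-free, fully acquired rule follower."""
    return AgentParams(weber=1e-3, lapse=0.0, q0=1.0, acquisition=0.0,
                       load_penalty=0.0)


# -- parameter recovery -----------------------------------------------------

def fit_weber(counts: dict, fit_lapse: bool = True,
              w0: float = 0.3) -> dict:
    """Maximum-likelihood Weber fraction from per-contrast choice counts.

    ``counts`` maps (n_small, n_large) -> (n_correct, n_total). The lapse
    rate is jointly estimated by default (bounded via a logit transform).
    Returns {"weber", "lapse", "loglik"}.
    """
    items = [(ns, nl, int(k), int(n)) for (ns, nl), (k, n) in counts.items()]
    if not items or all(n == 0 for *_, n in items):
        raise ValueError("no choices to fit")

    def nll(theta):
        w = math.exp(theta[0])
        lam = 1.0 / (1.0 + math.exp(-theta[1])) * 0.5 if fit_lapse else 0.0
        total = 0.0
        for ns, nl, k, n in items:
            p = p_correct_numerosity(ns, nl, w, lam)
            p = min(max(p, 1e-12), 1 - 1e-12)
            total -= k * math.log(p) + (n - k) * math.log(1 - p)
        return total

    x0 = [math.log(w0), -3.0]
    res = minimize(nll, x0 if fit_lapse else x0[:1],
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    w = math.exp(res.x[0])
    lam = (1.0 / (1.0 + math.exp(-res.x[1])) * 0.5) if fit_lapse else 0.0
    return {"weber": w, "lapse": lam, "loglik": -float(res.fun)}
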