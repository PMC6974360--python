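"""Dual Rescorla-Wagner learner with volatility-specific learning rates.

Two delta-rule predictors run in parallel over a session:

* an *experienced-value* learner tracking V_exp = P(blue rewarded) from
  the outcome indicator, and
* an *inferred-value* learner tracking V_inf = P(advice correct) from
  the agreement between the advice frame and the outcome.

Each learner uses a separate learning rate in stable and volatile phases
of its own schedule (four rates in the full model).  The advice frame is
converted into a blue-choice probability, V_iaw = |advice - V_inf|
(advice coded 0 = blue, 1 = green), mixed with the experienced value by a
weight zeta,

    vB = zeta * V_iaw + (1 - zeta) * V_exp,

and mapped to a blue-choice probability by the unit-square sigmoid

    P(blue) = vB**beta / (vB**beta + (1 - vB)**beta),

where beta > 0 is the inverse decision temperature.  Nested variants:
M1 uses a single learning rate, M2 separates stable/volatile only, and
M3 (the full model) separates all four rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .task import STABLE, VOLATILE, TaskSchedule, TrialSequence

VARIANTS = ("M1", "M2", "M3")

_VB_EPS = 1e-12  # clip bound before the sigmoid powers; guards 0/0


@dataclass(frozen=True)
class ModelParams:
    """Native-space parameters of the dual learner.

    Variant constraints: M1 requires all four learning rates equal; M2
    requires experienced == inferred within each volatility level.
    """

    alpha_stable_experienced: float
    alpha_volatile_experienced: float
    alpha_stable_inferred: float
    alpha_volatile_inferred: float
    beta: float
    zeta: float
    variant: str = "M3"

    def __post_init__(self) -> None:
        for name in ("alpha_stable_experienced", "alpha_volatile_experienced",
                     "alpha_stable_inferred", "alpha_volatile_inferred"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name}={a} must lie strictly in (0, 1)")
        if not self.beta > 0.0:
            raise ValueError(f"beta={self.beta} must be > 0")
        if not 0.0 < self.zeta < 1.0:
            raise ValueError(f"zeta={self.zeta} must lie strictly in (0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "M1":
            alphas = {self.alpha_stable_experienced, self.alpha_volatile_experienced,
                      self.alpha_stable_inferred, self.alpha_volatile_inferred}
            if len(alphas) != 1:
                raise ValueError("M1 requires all four learning rates equal")
        elif self.variant == "M2":
            if (self.alpha_stable_experienced != self.alpha_stable_inferred
                    or self.alpha_volatile_experienced != self.alpha_volatile_inferred):
                raise ValueError("M2 requires experienced == inferred rates per phase")

    @classmethod
    def m1(cls, alpha: float, beta: float, zeta: float) -> "ModelParams":
        return cls(alpha, alpha, alpha, alpha, beta, zeta, variant="M1")

    @classmethod
    def m2(cls, alpha_stable: float, alpha_volatile: float,
           beta: float, zeta: float) -> "ModelParams":
        return cls(alpha_stable, alpha_volatile, alpha_stable, alpha_volatile,
                   beta, zeta, variant="M2")


@dataclass
class LearnerState:
    """Current value estimates of the two predictors (both start at 0.5)."""

    v_experienced: float = 0.5
    v_inferred: float = 0.5


@dataclass
class ModelTrace:
    """Per-trial quantities from a forward run of the model."""

    v_experienced: np.ndarray
    v_inferred: np.ndarray
    v_inferred_advice_weighted: np.ndarray
    vb: np.ndarray
    p_blue: np.ndarray
    p_chosen: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.p_blue)

    def to_frame(self):
        import pandas as pd

        data = {
            "trial": np.arange(1, self.n_trials + 1),
            "v_experienced": self.v_experienced,
            "v_inferred": self.v_inferred,
            "v_inferred_advice_weighted": self.v_inferred_advice_weighted,
            "vb": self.vb,
            "p_blue": self.p_blue,
        }
        if self.p_chosen is not None:
            data["p_chosen"] = self.p_chosen
        return pd.DataFrame(data)


def delta_update(v: float, r: float, alpha: float) -> float:
    """Rescorla-Wagner delta rule: V <- V + alpha * (r - V)."""
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"value {v} outside [0, 1]")
    if r not in (0, 1, 0.0, 1.0):
        raise ValueError(f"reinforcement signal {r} must be 0 or 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    return v + alpha * (r - v)


def select_alpha(params: ModelParams, learning_type: str, volatility_label: str) -> float:
    """Learning rate for a (learning type, volatility) cell."""
    if learning_type not in ("experienced", "inferred"):
        raise ValueError(f"unknown learning type {learning_type!r}")
    if volatility_label not in (STABLE, VOLATILE):
        raise ValueError(f"unknown volatility label {volatility_label!r}")
    return getattr(params, f"alpha_{volatility_label}_{learning_type}")


def advice_to_blue_prob(advice: int, v_inferred: float) -> float:
    """Blue-reward probability implied by the advice frame.

    With advice coded 0 = blue and 1 = green, this is |advice - V_inf|:
    advice on blue with veracity v supports blue with probability v;
    advice on green with veracity v supports blue with probability 1 - v.
    """
    if advice not in (0, 1):
        raise ValueError("advice must be 0 (blue) or 1 (green)")
    if not 0.0 <= v_inferred <= 1.0:
        raise ValueError("v_inferred must lie in [0, 1]")
    return abs(advice - v_inferred)


def integrate_values(v_inferred_weighted: float, v_experienced: float, zeta: float) -> float:
    """Convex combination of advice-derived and experience-derived value."""
    return zeta * v_inferred_weighted + (1.0 - zeta) * v_experienced


def choice_probability(vb: float, beta: float) -> float:
    """Unit-square sigmoid P(blue) = vb**beta / (vb**beta + (1-vb)**beta).

    Evaluated in log-odds space for numerical stability at large beta;
    vb exactly 0 or 1 map to 0 or 1.
    """
    if not 0.0 <= vb <= 1.0:
        raise ValueError("vb must lie in [0, 1]")
    if not beta > 0:
        raise ValueError("beta must be > 0")
    if vb == 0.0:
        return 0.0
    if vb == 1.0:
        return 1.0
    vb = min(max(vb, _VB_EPS), 1.0 - _VB_EPS)
    return float(expit(beta * (np.log(vb) - np.log1p(-vb))))


def run_model(
    params: ModelParams,
    trials: TrialSequence,
    reward_schedule: TaskSchedule,
    advice_schedule: TaskSchedule,
) -> ModelTrace:
    """Run the dual learner forward over one session.

    Ordering per trial i: predict (V_iaw, vB, P(blue)) from the values
    carried in from trials < i, then update V_exp from the outcome and
    V_inf from advice correctness.  Updates occur regardless of choice
    (the outcome indicator is always shown, so both reinforcement signals
    are observable on every trial).
    """
    n = trials.n_trials
    if reward_schedule.n_trials != n or advice_schedule.n_trials != n:
        raise ValueError("schedule lengths do not match the trial sequence")
    reward_vol = reward_schedule.per_trial_volatility
    advice_vol = advice_schedule.per_trial_volatility

    a_exp = {STABLE: params.alpha_stable_experienced, VOLATILE: params.alpha_volatile_experienced}
    a_inf = {STABLE: params.alpha_stable_inferred, VOLATILE: params.alpha_volatile_inferred}
    beta, zeta = params.beta, params.zeta

    outcome = trials.outcome
    advice = trials.advice
    advice_correct = trials.advice_correct

    v_exp_tr = np.empty(n)
    v_inf_tr = np.empty(n)
    v_iaw_tr = np.empty(n)
    vb_tr = np.empty(n)

    v_exp, v_inf = 0.5, 0.5
    for i in range(n):
        v_iaw = abs(advice[i] - v_inf)
        vb = zeta * v_iaw + (1.0 - zeta) * v_exp
        v_exp_tr[i] = v_exp
        v_inf_tr[i] = v_inf
        v_iaw_tr[i] = v_iaw
        vb_tr[i] = vb
        v_exp += a_exp[reward_vol[i]] * (outcome[i] - v_exp)
        v_inf += a_inf[advice_vol[i]] * (advice_correct[i] - v_inf)

    vb_clipped = np.clip(vb_tr, _VB_EPS, 1.0 - _VB_EPS)
    p_blue = expit(beta * (np.log(vb_clipped) - np.log1p(-vb_clipped)))

    p_chosen = None
    if trials.choice is not None:
        p_chosen = np.where(trials.choice == 1, p_blue, 1.0 - p_blue)
    return ModelTrace(v_exp_tr, v_inf_tr, v_iaw_tr, vb_tr, p_blue, p_chosen)


def log_likelihood(
    params: ModelParams,
    trials: TrialSequence,
    reward_schedule: TaskSchedule,
    advice_schedule: TaskSchedule,
) -> float:
    """Sum of log choice probabilities under the model; -inf if any
    observed choice has probability zero."""
    if trials.choice is None:
        raise ValueError("log_likelihood requires observed choices")
    trace = run_model(params, trials, reward_schedule, advice_schedule)
    # log P(chosen) evaluated in log-odds space: with x = beta*logit(vb),
    # log P(blue) = -log(1 + e^-x); avoids underflow at large beta
    vb = np.clip(trace.vb, _VB_EPS, 1.0 - _VB_EPS)
    x = params.beta * (np.log(vb) - np.log1p(-vb))
    sign = np.where(trials.choice == 1, 1.0, -1.0)
    loglik = -np.logaddexp(0.0, -sign * x)
    if np.any(trace.p_chosen == 0.0):
        # a literally impossible choice (vb exactly 0 or 1 against it)
        if np.any(trace.vb[trials.choice == 1] == 0.0) or np.any(
            trace.vb[trials.choice == 0] == 1.0
        ):
            return -np.inf
    return float(np.sum(loglik))
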