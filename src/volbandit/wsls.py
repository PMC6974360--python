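"""Win-stay/lose-shift (WSLS) predicted-choice regressors and per-cell
regression coefficients.

For each trial after the first, a WSLS regressor encodes the choice a
strict win-stay/lose-shift strategist would make given the previous
trial:

* experienced cells — stay with the previous colour after a win
  (previous choice matched the outcome), switch colour after a loss;
  coded 1 = blue, 0 = green;
* inferred cells — repeat the previous follow/deviate decision after a
  win, reverse it after a loss; coded 1 = follow the advice frame,
  0 = deviate.

Regressing the participant's actual coding on the predicted coding,
separately within stable and volatile trials of the relevant schedule
and separately per session, yields the per-participant beta_WSLS table
(8 coefficients for a two-session participant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task import STABLE, VOLATILE, SessionRecord, TaskSchedule, TrialSequence

LEARNING_TYPES = ("experienced", "inferred")


def wsls_regressor(
    choices: np.ndarray,
    outcomes: np.ndarray,
    advice: np.ndarray,
    learning_type: str,
) -> np.ndarray:
    """Predicted-choice sequence; trial 0 is NaN (no previous trial).

    A win on trial i-1 means the choice matched the outcome indicator.
    """
    choices = np.asarray(choices, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    advice = np.asarray(advice, dtype=float)
    n = len(choices)
    if len(outcomes) != n or len(advice) != n:
        raise ValueError("choices/outcomes/advice lengths differ")
    won = choices == outcomes
    pred = np.full(n, np.nan)
    if learning_type == "experienced":
        pred[1:] = np.where(won[:-1], choices[:-1], 1.0 - choices[:-1])
    elif learning_type == "inferred":
        followed = (choices == 1.0 - advice).astype(float)
        pred[1:] = np.where(won[:-1], followed[:-1], 1.0 - followed[:-1])
    else:
        raise ValueError(f"unknown learning type {learning_type!r}")
    return pred


def _cell_slope(y: np.ndarray, x: np.ndarray, model_family: str) -> tuple[float | None, str]:
    """Univariate regression slope of y on x with intercept; returns
    (slope or None, reason)."""
    if len(np.unique(x)) < 2:
        return None, "constant predictor"
    if len(np.unique(y)) < 2:
        return None, "constant response"
    import statsmodels.api as sm

    X = sm.add_constant(x)
    if model_family == "linear":
        return float(sm.OLS(y, X).fit().params[1]), "ok"
    if model_family == "logistic":
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception:
            return None, "separation"
        if not np.all(np.isfinite(res.params)):
            return None, "separation"
        return float(res.params[1]), "ok"
    raise ValueError(f"model_family must be 'linear' or 'logistic', got {model_family!r}")


@dataclass
class WSLSBetas:
    """Per-cell WSLS regression coefficients for one participant.

    Keys are (session, volatility, learning_type) tuples.
    """

    beta: dict[tuple[str, str, str], float | None]
    n_trials_per_cell: dict[tuple[str, str, str], int]
    reasons: dict[tuple[str, str, str], str]
    model_family: str
    min_trials: int = 10

    def to_frame(self, participant=None) -> pd.DataFrame:
        rows = []
        for (session, vol, ltype), b in self.beta.items():
            rows.append(
                {
                    "participant": participant,
                    "session": session,
                    "volatility": vol,
                    "learning_type": ltype,
                    "beta": b,
                    "n_trials": self.n_trials_per_cell[(session, vol, ltype)],
                    "reason": self.reasons[(session, vol, ltype)],
                    "model_family": self.model_family,
                }
            )
        return pd.DataFrame(rows)


def _iter_cells(sessions: Mapping[str, tuple]):
    for session_label, (trials, reward_sched, advice_sched) in sessions.items():
        if trials.choice is None:
            raise ValueError(f"session {session_label!r} has no choices")
        for ltype in LEARNING_TYPES:
            sched = reward_sched if ltype == "experienced" else advice_sched
            labels = sched.per_trial_volatility
            for vol in (STABLE, VOLATILE):
                # trial i is assigned by the phase label at i; trial 0 has
                # no previous trial and is excluded
                mask = (labels == vol)
                mask[0] = False
                yield session_label, ltype, vol, trials, mask


def sessions_mapping(records: Sequence[SessionRecord]) -> dict[str, tuple]:
    """Build the {session_label: (trials, reward, advice)} mapping for one
    participant's records."""
    return {
        rec.session_id: (rec.trials, rec.reward_schedule, rec.advice_schedule)
        for rec in records
    }


def fit_wsls_betas(
    sessions: Mapping[str, tuple],
    model_family: str = "linear",
    min_trials: int = 10,
) -> WSLSBetas:
    """Estimate the per-cell WSLS coefficients for one participant.

    ``sessions`` maps a session label (e.g. drug condition) to a
    ``(TrialSequence, reward_schedule, advice_schedule)`` tuple.  Cells
    with fewer than ``min_trials`` usable trials, or a constant predictor
    or response, carry a None coefficient with the reason recorded.
    """
    betas: dict = {}
    counts: dict = {}
    reasons: dict = {}
    for session_label, ltype, vol, trials, mask in _iter_cells(sessions):
        pred = wsls_regressor(trials.choice, trials.outcome, trials.advice, ltype)
        if ltype == "experienced":
            response = trials.choice.astype(float)
        else:
            response = trials.followed_advice.astype(float)
        x = pred[mask]
        y = response[mask]
        key = (session_label, vol, ltype)
        counts[key] = int(mask.sum())
        if counts[key] < min_trials:
            betas[key], reasons[key] = None, "too few trials"
            continue
        betas[key], reasons[key] = _cell_slope(y, x, model_family)
    return WSLSBetas(betas, counts, reasons, model_family, min_trials)


def ws_ls_rates(sessions: Mapping[str, tuple]) -> pd.DataFrame:
    """Per-cell win-stay and lose-shift proportions with counts.

    Stay means repeating the previous coding (colour for experienced
    cells, follow/deviate for inferred cells); win/loss refers to whether
    the previous choice was rewarded.  Undefined proportions (no wins or
    no losses in a cell) are NaN.
    """
    rows = []
    for session_label, ltype, vol, trials, mask in _iter_cells(sessions):
        choices = trials.choice.astype(int)
        won = choices == trials.outcome
        if ltype == "experienced":
            coding = choices.astype(float)
        else:
            coding = trials.followed_advice.astype(float)
        stayed = np.full(len(choices), np.nan)
        stayed[1:] = (coding[1:] == coding[:-1]).astype(float)
        prev_won = np.zeros(len(choices), dtype=bool)
        prev_won[1:] = won[:-1]
        win_mask = mask & prev_won
        loss_mask = mask & ~prev_won
        loss_mask[0] = False
        n_win, n_loss = int(win_mask.sum()), int(loss_mask.sum())
        rows.append(
            {
                "session": session_label,
                "volatility": vol,
                "learning_type": ltype,
                "win_stay": float(np.mean(stayed[win_mask])) if n_win else np.nan,
                "lose_shift": float(1.0 - np.mean(stayed[loss_mask])) if n_loss else np.nan,
                "n_win": n_win,
                "n_loss": n_loss,
            }
        )
    return pd.DataFrame(rows)
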