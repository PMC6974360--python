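"""Win-stay/lose-shift regressors, per-cell betas, and WS/LS rates."""

import numpy as np
import pytest

from volbandit.task import STABLE, VOLATILE, TrialSequence
from volbandit.wsls import fit_wsls_betas, wsls_regressor, ws_ls_rates

from conftest import constant_schedule


def test_experienced_regressor_examples():
    # previous: chose blue and won -> stay blue (1); chose blue and lost
    # -> shift to green (0)
    choices = np.array([1, 0, 1, 0])
    outcomes = np.array([1, 1, 0, 0])
    advice = np.zeros(4, dtype=int)
    pred = wsls_regressor(choices, outcomes, advice, "experienced")
    assert np.isnan(pred[0])
    # trial 1: prev chose blue, outcome blue (win) -> 1
    # trial 2: prev chose green, outcome blue (loss) -> shift to blue = 1
    # trial 3: prev chose blue, outcome green (loss) -> shift to green = 0
    assert pred[1] == 1 and pred[2] == 1 and pred[3] == 0


def test_inferred_regressor_examples():
    # followed advice and lost -> deviate (0); followed and won -> follow (1)
    choices = np.array([1, 1, 0])
    advice = np.array([0, 0, 1])   # frame on blue, blue, green
    outcomes = np.array([0, 1, 1])  # trial 0: chose blue, lost
    pred = wsls_regressor(choices, outcomes, advice, "inferred")
    # trial 0: followed (choice blue, advice blue), lost -> predict deviate
    assert pred[1] == 0
    # trial 1: followed and won -> predict follow
    assert pred[2] == 1


def _wsls_perfect_session(n=120, seed=0, mode="experienced"):
    """Choices that follow the WSLS rule exactly."""
    rng = np.random.default_rng(seed)
    outcomes = rng.integers(0, 2, n)
    advice = rng.integers(0, 2, n)
    choices = np.empty(n, dtype=int)
    choices[0] = 1
    for i in range(1, n):
        if mode == "experienced":
            won = choices[i - 1] == outcomes[i - 1]
            choices[i] = choices[i - 1] if won else 1 - choices[i - 1]
        else:
            followed = choices[i - 1] == 1 - advice[i - 1]
            won = choices[i - 1] == outcomes[i - 1]
            follow_now = followed if won else not followed
            choices[i] = 1 - advice[i] if follow_now else advice[i]
    return TrialSequence(outcomes, advice, (advice == 1 - outcomes).astype(int),
                         choice=choices)


@pytest.mark.parametrize("ltype", ["experienced", "inferred"])
def test_perfect_wsls_agent_has_unit_slope(ltype):
    trials = _wsls_perfect_session(mode=ltype)
    reward = constant_schedule(0.75, 120, "reward", STABLE)
    advice_sched = constant_schedule(0.8, 120, "advice", STABLE)
    betas = fit_wsls_betas({"A": (trials, reward, advice_sched)}, model_family="linear")
    b = betas.beta[("A", STABLE, ltype)]
    assert b == pytest.approx(1.0)


def test_coin_flip_agent_slope_near_zero():
    rng = np.random.default_rng(1)
    n = 4000
    outcomes = rng.integers(0, 2, n)
    advice = rng.integers(0, 2, n)
    choices = rng.integers(0, 2, n)
    trials = TrialSequence(outcomes, advice, (advice == 1 - outcomes).astype(int),
                           choice=choices)
    reward = constant_schedule(0.75, n, "reward", STABLE)
    advice_sched = constant_schedule(0.8, n, "advice", STABLE)
    betas = fit_wsls_betas({"A": (trials, reward, advice_sched)})
    for ltype in ("experienced", "inferred"):
        assert abs(betas.beta[("A", STABLE, ltype)]) < 0.06


def test_cell_counts_partition_trials(session_data):
    trials, reward, advice_sched = session_data
    betas = fit_wsls_betas({"A": (trials, reward, advice_sched)})
    n = trials.n_trials
    for ltype in ("experienced", "inferred"):
        total = sum(betas.n_trials_per_cell[("A", vol, ltype)]
                    for vol in (STABLE, VOLATILE))
        assert total == n - 1  # first trial excluded


def test_linear_slope_equals_conditional_mean_difference(session_data):
    """OLS slope on a binary predictor is the difference of conditional
    response means (closed form)."""
    trials, reward, advice_sched = session_data
    betas = fit_wsls_betas({"A": (trials, reward, advice_sched)})
    pred = wsls_regressor(trials.choice, trials.outcome, trials.advice, "experienced")
    labels = reward.per_trial_volatility
    mask = (labels == STABLE)
    mask[0] = False
    x, y = pred[mask], trials.choice[mask].astype(float)
    closed = y[x == 1].mean() - y[x == 0].mean()
    assert betas.beta[("A", STABLE, "experienced")] == pytest.approx(closed)


def test_betas_invariant_to_colour_relabelling(session_data):
    trials, reward, advice_sched = session_data
    flipped = TrialSequence(1 - trials.outcome, 1 - trials.advice,
                            trials.advice_correct, choice=1 - trials.choice)
    a = fit_wsls_betas({"A": (trials, reward, advice_sched)})
    b = fit_wsls_betas({"A": (flipped, reward, advice_sched)})
    for key, val in a.beta.items():
        assert b.beta[key] == pytest.approx(val, abs=1e-9)


def test_logistic_family_runs(session_data):
    trials, reward, advice_sched = session_data
    betas = fit_wsls_betas({"A": (trials, reward, advice_sched)},
                           model_family="logistic")
    defined = [v for v in betas.beta.values() if v is not None]
    assert len(defined) >= 2
    assert all(np.isfinite(v) for v in defined)


def test_ws_ls_rates_extremes_and_hand_tally():
    # perfect WSLS agent: both proportions 1.0
    trials = _wsls_perfect_session(mode="experienced", n=60)
    reward = constant_schedule(0.75, 60, "reward", STABLE)
    advice_sched = constant_schedule(0.8, 60, "advice", STABLE)
    rates = ws_ls_rates({"A": (trials, reward, advice_sched)})
    row = rates[(rates.learning_type == "experienced") & (rates.volatility == STABLE)]
    assert row.win_stay.item() == 1.0 and row.lose_shift.item() == 1.0

    # always-blue agent: win-stay 1.0, lose-shift 0.0
    n = 30
    rng = np.random.default_rng(2)
    outcomes = rng.integers(0, 2, n)
    advice = rng.integers(0, 2, n)
    trials = TrialSequence(outcomes, advice, (advice == 1 - outcomes).astype(int),
                           choice=np.ones(n, dtype=int))
    reward = constant_schedule(0.75, n, "reward", STABLE)
    advice_sched = constant_schedule(0.8, n, "advice", STABLE)
    rates = ws_ls_rates({"A": (trials, reward, advice_sched)})
    row = rates[(rates.learning_type == "experienced") & (rates.volatility == STABLE)]
    assert row.win_stay.item() == 1.0 and row.lose_shift.item() == 0.0

    # 12-trial hand tally
    choices = np.array([1, 1, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1])
    outcomes = np.array([1, 0, 0, 1, 1, 1, 0, 0, 1, 0, 1, 0])
    advice = np.zeros(12, dtype=int)
    trials = TrialSequence(outcomes, advice, (advice == 1 - outcomes).astype(int),
                           choice=choices)
    reward = constant_schedule(0.75, 12, "reward", STABLE)
    advice_sched = constant_schedule(0.8, 12, "advice", STABLE)
    rates = ws_ls_rates({"A": (trials, reward, advice_sched)})
    row = rates[(rates.learning_type == "experienced") & (rates.volatility == STABLE)]
    # wins (choice==outcome) on trials {0,2,4,5,7,9,10} -> successors
    # {1,3,5,6,8,10,11}; stays there: 1,3,5,6,8,11 stay, 10 shifts (1 vs 0)
    assert row.n_win.item() == 7
    assert row.win_stay.item() == pytest.approx(6 / 7)
    # losses on trials {1,3,6,8} -> successors {2,4,7,9}; shifts at 2,4,7,
    # stay at 9
    assert row.n_loss.item() == 4
    assert row.lose_shift.item() == pytest.approx(3 / 4)


def test_high_learning_rate_agent_has_larger_experienced_beta(schedules):
    """WSLS weight tracks learning rate: a fast learner behaves more like
    a win-stay/lose-shift strategist than a slow learner."""
    from volbandit.model import ModelParams
    from volbandit.task import generate_advice, generate_outcomes, simulate_agent

    reward, advice_sched = schedules
    rng = np.random.default_rng(3)
    slopes = {}
    for label, alpha in (("fast", 0.85), ("slow", 0.05)):
        vals = []
        for _ in range(10):
            params = ModelParams(alpha, alpha, alpha, alpha, beta=6.0, zeta=0.2)
            outcomes = generate_outcomes(reward, rng=rng)
            advice, _ = generate_advice(advice_sched, outcomes, rng=rng)
            trials = simulate_agent(params, reward, advice_sched, outcomes, advice, rng=rng)
            betas = fit_wsls_betas({"A": (trials, reward, advice_sched)})
            cell = [betas.beta[("A", vol, "experienced")] for vol in (STABLE, VOLATILE)]
            vals.extend(v for v in cell if v is not None)
        slopes[label] = np.mean(vals)
    assert slopes["fast"] > slopes["slow"]
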