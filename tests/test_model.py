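"""Dual Rescorla-Wagner learner and action selector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volbandit.model import (
    ModelParams,
    advice_to_blue_prob,
    choice_probability,
    delta_update,
    integrate_values,
    log_likelihood,
    run_model,
    select_alpha,
)
from volbandit.task import TrialSequence, generate_advice, generate_outcomes

from conftest import constant_schedule, tiny_session


@pytest.mark.parametrize(
    "v, r, alpha, expected",
    [(0.5, 1, 0.2, 0.6), (0.3, 0, 0.999999, pytest.approx(0.0, abs=1e-5)),
     (0.7, 1, 0.5, 0.85)],
)
def test_delta_update_values(v, r, alpha, expected):
    assert delta_update(v, r, alpha) == pytest.approx(expected)


def test_delta_update_zero_prediction_error():
    for v in (0.0, 1.0):
        assert delta_update(v, v, 0.37) == v


def test_delta_update_validates_inputs():
    with pytest.raises(ValueError):
        delta_update(1.2, 1, 0.2)
    with pytest.raises(ValueError):
        delta_update(0.5, 0.3, 0.2)
    with pytest.raises(ValueError):
        delta_update(0.5, 1, 1.0)


def test_select_alpha_respects_variants():
    m1 = ModelParams.m1(0.3, 2.0, 0.5)
    assert len({select_alpha(m1, lt, vol) for lt in ("experienced", "inferred")
                for vol in ("stable", "volatile")}) == 1
    m2 = ModelParams.m2(0.1, 0.5, 2.0, 0.5)
    assert select_alpha(m2, "inferred", "stable") == select_alpha(m2, "experienced", "stable")
    m3 = ModelParams(0.1, 0.2, 0.3, 0.4, 2.0, 0.5)
    assert select_alpha(m3, "experienced", "volatile") == 0.2
    assert select_alpha(m3, "inferred", "stable") == 0.3


def test_variant_constraints_enforced():
    with pytest.raises(ValueError):
        ModelParams(0.1, 0.2, 0.1, 0.2, 2.0, 0.5, variant="M1")
    with pytest.raises(ValueError):
        ModelParams(0.1, 0.2, 0.3, 0.2, 2.0, 0.5, variant="M2")


@pytest.mark.parametrize(
    "advice, v_inf, expected",
    [(1, 0.80, 0.2), (0, 0.80, 0.8), (1, 0.5, 0.5), (0, 0.0, 0.0)],
)
def test_advice_to_blue_prob(advice, v_inf, expected):
    """Advice on green with veracity 0.8 supports blue with 0.2."""
    assert advice_to_blue_prob(advice, v_inf) == pytest.approx(expected)


def test_integrate_values_is_convex_combination():
    assert integrate_values(0.2, 0.6, 0.0) == 0.6
    assert integrate_values(0.2, 0.6, 1.0) == 0.2
    assert integrate_values(0.2, 0.6, 0.5) == pytest.approx(0.4)


def test_choice_probability_values():
    assert choice_probability(0.5, 17.0) == 0.5
    assert choice_probability(0.73, 1.0) == pytest.approx(0.73)
    # 0.8^3 / (0.8^3 + 0.2^3) = 0.512 / 0.520
    assert choice_probability(0.8, 3.0) == pytest.approx(0.512 / 0.520)
    assert choice_probability(0.0, 5.0) == 0.0
    assert choice_probability(1.0, 5.0) == 1.0
    # step-function limit at very large beta
    assert choice_probability(0.9, 1e6) == pytest.approx(1.0)
    assert choice_probability(0.1, 1e6) == pytest.approx(0.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(vb=st.floats(1e-9, 1.0 - 1e-9), beta=st.floats(0.01, 100.0))
def test_choice_probability_symmetry(vb, beta):
    p = choice_probability(vb, beta)
    q = choice_probability(1.0 - vb, beta)
    assert 0.0 <= p <= 1.0
    assert p + q == pytest.approx(1.0, abs=1e-9)


def test_run_model_no_learning_from_flat_prior(session_data):
    trials, reward, advice_sched = session_data
    params = ModelParams(1e-9, 1e-9, 1e-9, 1e-9, beta=2.0, zeta=0.5)
    trace = run_model(params, trials, reward, advice_sched)
    assert np.allclose(trace.p_blue, 0.5, atol=1e-6)


def test_run_model_fixed_point_under_stationary_outcomes():
    """With stationary Bernoulli(0.8) outcomes the experienced value
    settles around the outcome mean (fixed point of the delta rule)."""
    n = 1000
    reward = constant_schedule(0.8, n)
    advice_sched = constant_schedule(0.5, n, "advice")
    outcomes = generate_outcomes(reward, seed=0)
    advice, correct = generate_advice(advice_sched, outcomes, seed=1)
    trials = TrialSequence(outcomes, advice, correct)
    params = ModelParams(0.1, 0.1, 0.1, 0.1, beta=1.0, zeta=0.5)
    trace = run_model(params, trials, reward, advice_sched)
    assert abs(trace.v_experienced[200:].mean() - 0.8) < 0.05


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 9999),
    a=st.floats(0.01, 0.99), b=st.floats(0.01, 0.99),
    c=st.floats(0.01, 0.99), d=st.floats(0.01, 0.99),
    beta=st.floats(0.1, 50.0), zeta=st.floats(0.01, 0.99),
)
def test_trace_bounds_property(seed, a, b, c, d, beta, zeta):
    """All trace quantities stay in [0, 1] under arbitrary parameters."""
    trials, reward, advice_sched = tiny_session(n=40, seed=seed)
    params = ModelParams(a, b, c, d, beta, zeta)
    trace = run_model(params, trials, reward, advice_sched)
    for arr in (trace.v_experienced, trace.v_inferred,
                trace.v_inferred_advice_weighted, trace.vb, trace.p_blue):
        assert np.all((arr >= 0.0) & (arr <= 1.0))


def test_zeta_zero_ignores_advice(session_data):
    trials, reward, advice_sched = session_data
    params = ModelParams(0.2, 0.4, 0.2, 0.4, beta=3.0, zeta=1e-12)
    trace_a = run_model(params, trials, reward, advice_sched)
    flipped = TrialSequence(
        trials.outcome, 1 - trials.advice,
        (1 - trials.advice == 1 - trials.outcome).astype(int),
    )
    trace_b = run_model(params, flipped, reward, advice_sched)
    assert np.allclose(trace_a.p_blue, trace_b.p_blue, atol=1e-9)


def test_m3_with_equal_alphas_reproduces_m1(session_data):
    trials, reward, advice_sched = session_data
    m3 = ModelParams(0.3, 0.3, 0.3, 0.3, beta=2.0, zeta=0.4)
    m1 = ModelParams.m1(0.3, 2.0, 0.4)
    trace_a = run_model(m3, trials, reward, advice_sched)
    trace_b = run_model(m1, trials, reward, advice_sched)
    assert np.array_equal(trace_a.p_blue, trace_b.p_blue)


def _brute_force_loglik(params, trials, reward, advice_sched):
    """Trial-by-trial product oracle, written independently of run_model."""
    v_exp, v_inf = 0.5, 0.5
    total = 0.0
    r_lab = reward.per_trial_volatility
    a_lab = advice_sched.per_trial_volatility
    for i in range(trials.n_trials):
        viaw = abs(trials.advice[i] - v_inf)
        vb = params.zeta * viaw + (1 - params.zeta) * v_exp
        p_blue = vb ** params.beta / (vb ** params.beta + (1 - vb) ** params.beta)
        p = p_blue if trials.choice[i] == 1 else 1 - p_blue
        total += np.log(p)
        ae = params.alpha_stable_experienced if r_lab[i] == "stable" \
            else params.alpha_volatile_experienced
        ai = params.alpha_stable_inferred if a_lab[i] == "stable" \
            else params.alpha_volatile_inferred
        v_exp = v_exp + ae * (trials.outcome[i] - v_exp)
        v_inf = v_inf + ai * (trials.advice_correct[i] - v_inf)
    return total


def test_log_likelihood_matches_brute_force_oracle():
    trials, reward, advice_sched = tiny_session(n=5, seed=3)
    params = ModelParams(0.15, 0.45, 0.25, 0.35, beta=2.5, zeta=0.6)
    expected = _brute_force_loglik(params, trials, reward, advice_sched)
    assert log_likelihood(params, trials, reward, advice_sched) == pytest.approx(expected)


def test_log_likelihood_chance_and_monotone():
    n = 20
    trials, reward, advice_sched = tiny_session(n=n, seed=4)
    flat = ModelParams(1e-9, 1e-9, 1e-9, 1e-9, beta=2.0, zeta=0.5)
    assert log_likelihood(flat, trials, reward, advice_sched) == pytest.approx(n * np.log(0.5))
    # an extra trial can only decrease the total log-probability
    longer, reward2, advice2 = tiny_session(n=n + 1, seed=4)
    assert log_likelihood(flat, longer, reward2, advice2) <= \
        log_likelihood(flat, trials, reward, advice_sched)
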