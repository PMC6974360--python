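import numpy as np
import pytest

from volbandit.model import ModelParams
from volbandit.task import (
    PhaseSegment,
    TaskSchedule,
    TrialSequence,
    generate_advice,
    generate_outcomes,
    generate_schedule,
    simulate_agent,
)


def constant_schedule(p: float, n: int, kind: str = "reward",
                      label: str = "stable") -> TaskSchedule:
    """Single-segment schedule with an arbitrary probability (test-only)."""
    return TaskSchedule(n, (PhaseSegment(0, n, p, label),), kind)


@pytest.fixture(scope="session")
def schedules():
    reward = generate_schedule(120, "reward", stable_first=True, seed=1)
    advice = generate_schedule(120, "advice", stable_first=False, seed=2)
    return reward, advice


@pytest.fixture(scope="session")
def agent_params():
    return ModelParams(0.2, 0.4, 0.2, 0.4, beta=3.0, zeta=0.5)


@pytest.fixture(scope="session")
def session_data(schedules, agent_params):
    """One simulated session with choices, at moderate parameters."""
    reward, advice_sched = schedules
    outcomes = generate_outcomes(reward, seed=3)
    advice, _ = generate_advice(advice_sched, outcomes, seed=4)
    trials = simulate_agent(agent_params, reward, advice_sched, outcomes, advice, seed=5)
    return trials, reward, advice_sched


def tiny_session(n: int = 5, seed: int = 0):
    """A short hand-checkable session on constant schedules."""
    rng = np.random.default_rng(seed)
    reward = constant_schedule(0.75, n, "reward", "stable")
    advice_sched = constant_schedule(0.8, n, "advice", "volatile")
    outcomes = rng.integers(0, 2, n)
    advice = rng.integers(0, 2, n)
    correct = (advice == 1 - outcomes).astype(int)
    choices = rng.integers(0, 2, n)
    trials = TrialSequence(outcomes, advice, correct, choice=choices)
    return trials, reward, advice_sched
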