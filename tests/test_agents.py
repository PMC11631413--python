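"""Value-function contract, exploration schedule and TD updates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pggq.agents import (
    AgentStateError,
    LearningConfig,
    NeuralQ,
    QPair,
    TabularQ,
    TrainingDivergenceError,
    Transition,
    epsilon_schedule,
    select_action,
    select_actions,
    td_target,
    train_vs_random,
)
from pggq.closed_form import random_opponent_q
from pggq.game import GameConfig, Observation, ProfileError


# ---------------------------------------------------------------- schedule
@pytest.mark.parametrize("t, expected", [(0, 0.251), (24, 0.011)])
def test_epsilon_schedule_values(t, expected):
    assert epsilon_schedule(t, LearningConfig()) == pytest.approx(expected)


@given(t=st.integers(0, 10_000))
def test_epsilon_schedule_monotone_and_bounded(t):
    cfg = LearningConfig()
    lo, hi = cfg.epsilon_floor, cfg.epsilon_floor + cfg.epsilon_amplitude
    e = epsilon_schedule(t, cfg)
    assert lo < e <= hi
    assert epsilon_schedule(t + 1, cfg) < e


def test_epsilon_schedule_rejects_negative_game_index():
    with pytest.raises(ValueError):
        epsilon_schedule(-1, LearningConfig())


# ---------------------------------------------------------------- selection
def test_greedy_selection_and_nan_rejection(rng):
    assert select_action(QPair(q_cooperate=0.2, q_defect=1.0), 0.0, rng) == 0
    assert select_action(QPair(q_cooperate=1.0, q_defect=0.2), 0.0, rng) == 1
    with pytest.raises(AgentStateError):
        select_action(QPair(float("nan"), 0.0), 0.0, rng)


@pytest.mark.parametrize("epsilon, q", [(1.0, (0.0, 9.9)), (0.0, (0.3, 0.3))])
def test_random_and_tie_break_frequencies(rng, epsilon, q):
    """Pure exploration and exact ties both yield ~50% cooperation."""
    qv = np.tile([q[0], q[1]], (4000, 1))
    if epsilon == 0.0:
        qv[:, 0] = qv[:, 1]  # force ties
    freq = select_actions(qv, epsilon, rng).mean()
    assert freq == pytest.approx(0.5, abs=0.03)


# ---------------------------------------------------------------- td target
def test_td_target_examples():
    vf = TabularQ(n_players=2)
    vf.table[0, :, :, 1] = 0.2  # QC
    vf.table[0, :, :, 0] = 1.0  # QD
    tr = Transition(Observation(0, 0.0), 0, 0.1, Observation(0, 1.0))
    assert td_target(tr, vf, 0.9) == pytest.approx(1.0)
    assert td_target(tr, vf, 0.0) == pytest.approx(0.1)
    zero = TabularQ(n_players=2)
    assert td_target(Transition(Observation(0, 0.0), 0, 0.0,
                                Observation(0, 0.0)), zero, 0.7) == 0.0


# ---------------------------------------------------------------- tabular
def test_tabular_zero_rate_is_identity():
    vf = TabularQ(n_players=3)
    vf.table += 0.5
    before = vf.table.copy()
    tr = Transition(Observation(1, 0.5), 1, 2.0, Observation(1, 1.0))
    vf.update([tr], LearningConfig(learning_rate=0.0))
    np.testing.assert_array_equal(vf.table, before)


def test_tabular_unit_rate_hits_target():
    """With eta = 1 the visited cell becomes r + gamma * max Q(s')."""
    vf = TabularQ(n_players=2)
    vf.table[0, 1, 1, :] = [3.0, 2.0]  # next state (C, k=1): max is 3.0
    tr = Transition(Observation(0, 0.0), 1, 0.5, Observation(1, 1.0))
    vf.update([tr], LearningConfig(learning_rate=1.0, discount=0.9))
    assert vf.table[0, 0, 0, 1] == pytest.approx(0.5 + 0.9 * 3.0)
    # only the visited cell changed
    assert np.count_nonzero(vf.table) == 3


def test_tabular_off_grid_observation_rejected():
    vf = TabularQ(n_players=5)
    with pytest.raises(ProfileError):
        vf.evaluate(Observation(0, 0.3))  # 0.3 not on k/4 grid


def test_tabular_recovers_closed_form_vs_random_opponents():
    """Q-learning against coin-flip opponents converges to the analytic
    value pair (stochastic; fixed seed, decaying per-cell step sizes)."""
    vf = TabularQ(n_players=2)
    cfg = LearningConfig(discount=0.9, tabular_visit_decay=True)
    train_vs_random(vf, GameConfig(2, 0.2), cfg, 60_000,
                    np.random.default_rng(7))
    truth = random_opponent_q(2, 0.2, 0.9)
    np.testing.assert_allclose(vf.table[0, :, :, 1], truth.q_cooperate, atol=0.03)
    np.testing.assert_allclose(vf.table[0, :, :, 0], truth.q_defect, atol=0.03)


# ---------------------------------------------------------------- neural
def test_neural_zero_rate_is_identity(rng):
    vf = NeuralQ(n_agents=1, rng=rng)
    obs = Observation(1, 0.5)
    before = vf.evaluate(obs)
    tr = Transition(Observation(0, 0.0), 0, 1.0, obs)
    vf.update([tr], LearningConfig(learning_rate=0.0))
    assert vf.evaluate(obs) == before


def test_neural_update_requires_nonempty_batch(rng):
    with pytest.raises(ValueError):
        NeuralQ(rng=rng).update([], LearningConfig())


def test_neural_supervised_regression_fits_grid_targets(rng):
    """A plain regression onto the analytic value pair over the full
    observation grid reaches MSE < 1e-3 well within 5000 steps."""
    vf = NeuralQ(n_agents=1, rng=rng)
    truth = random_opponent_q(2, 0.2, 0.9)
    prev = np.array([[0, 0, 1, 1, 0, 0, 1, 1]], dtype=float)
    frac = np.array([[0, 1, 0, 1, 0, 1, 0, 1]], dtype=float)
    acts = np.array([[0, 0, 0, 0, 1, 1, 1, 1]])
    targets = np.where(acts == 1, truth.q_cooperate, truth.q_defect)
    mse = np.inf
    for _ in range(5000):
        mse = vf.regress_step(prev, frac, acts, targets.astype(float), 0.01)
        if mse < 1e-3:
            break
    assert mse < 1e-3


def test_neural_learns_defection_against_random_opponents():
    """After the full session length vs forced-random opponents the net
    ranks defection above cooperation on >= 95% of grid observations."""
    hits, total = 0, 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        vf = NeuralQ(n_agents=1, rng=rng)
        train_vs_random(vf, GameConfig(2, 0.2), LearningConfig(), 600, rng)
        for a in (0, 1):
            for frac in (0.0, 1.0):
                q = vf.q_values(np.array([a]), np.array([frac]))[0]
                total += 1
                hits += q[0] > q[1]  # QD > QC
    assert hits / total >= 0.95


def test_neural_divergence_raises(rng):
    vf = NeuralQ(n_agents=1, rng=rng)
    prev = np.array([[0.0]])
    frac = np.array([[0.5]])
    acts = np.array([[1]])
    targets = np.array([[1e300]])
    with pytest.raises(TrainingDivergenceError):
        for _ in range(10):
            vf.regress_step(prev, frac, acts, targets, 1e30)


def test_neural_serialization_roundtrip(tmp_path, rng):
    vf = NeuralQ(n_agents=3, rng=rng)
    path = tmp_path / "params.npz"
    vf.save(path)
    clone = NeuralQ.load(path)
    prev = np.array([1, 0, 1])
    frac = np.array([0.0, 0.5, 1.0])
    np.testing.assert_array_equal(clone.q_values(prev, frac),
                                  vf.q_values(prev, frac))


def test_population_agents_are_independent(rng):
    """Updating from per-agent transitions must not leak gradients
    between agents: an agent whose target equals its own prediction
    keeps its value unchanged."""
    vf = NeuralQ(n_agents=2, rng=rng)
    prev = np.array([0.0, 1.0])
    frac = np.array([0.0, 1.0])
    before = vf.q_values(prev, frac)
    acts = np.array([0, 0])
    # agent 0 regresses toward its own current output (zero error),
    # agent 1 toward something far away
    targets = np.array([before[0, 0], 99.0])
    vf.regress_step(prev, frac, acts, targets, 0.05)
    after = vf.q_values(prev, frac)
    assert after[0, 0] == pytest.approx(before[0, 0], abs=1e-9)
    assert after[1, 0] != pytest.approx(before[1, 0], abs=1e-3)
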