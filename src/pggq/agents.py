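"""Independent Q-learning agents for the public goods game.

Each agent owns a value function mapping the two-component observation
``(previous own action, others' previous cooperation fraction)`` to a pair
of action values ``(QC, QD)``.  Actions are chosen epsilon-greedily and the
value function is regressed toward the one-step temporal-difference target

    y_t = r_t + gamma * max(Q(s_t, C), Q(s_t, D)),

the sampled form of the Bellman recursion for Q-learning.  The discount
factor ``gamma`` doubles as the per-period continuation probability of the
repeated game, so by default the final period of a game is *not* treated
as terminal (no masking of the bootstrap term).

Two interchangeable implementations are provided:

* :class:`TabularQ` — one table cell per grid observation; exact, used as
  the convergence reference.
* :class:`NeuralQ` — a small multilayer perceptron (2 inputs -> ReLU
  hidden layers -> 2 outputs) trained online with Adam.  This is the
  bounded-accuracy learner whose approximation error drives the
  cooperation phenomenology at large group sizes.

Both classes are natively vectorized over a *population* of agents with
independent parameters (``n_agents`` axis); the single-agent contract
(`evaluate` / `update`) operates on agent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .game import GameConfig, Observation, ProfileError

__all__ = [
    "AgentStateError",
    "LearningConfig",
    "NeuralQ",
    "QPair",
    "ReplayBuffer",
    "TabularQ",
    "TrainingDivergenceError",
    "Transition",
    "ValueFunction",
    "epsilon_schedule",
    "select_action",
    "select_actions",
    "td_target",
    "train_vs_random",
]

# action encoding throughout: index == contribution indicator g
ACTION_D = 0
ACTION_C = 1


class AgentStateError(RuntimeError):
    """The agent's value function produced unusable (NaN) values."""


class TrainingDivergenceError(RuntimeError):
    """Value-function parameters became non-finite during training."""


def _per_agent_2d(arr, dtype) -> np.ndarray:
    """Coerce to shape (A, B): a 1-D array is one sample per agent."""
    a = np.asarray(arr, dtype=dtype)
    return a[:, None] if a.ndim == 1 else a


class QPair(NamedTuple):
    """Action values for one observation."""

    q_cooperate: float
    q_defect: float


class Transition(NamedTuple):
    """One experience record ``(s_{t-1}, a_t, r_t, s_t)``.

    The environment's transition kernel is never represented explicitly;
    it is embodied by the sampled next observation, which reflects
    whatever the other agents actually did.
    """

    observation: Observation
    action: int
    reward: float
    next_observation: Observation


@dataclass
class LearningConfig:
    """Hyperparameters shared by all agents in a group.

    Parameters
    ----------
    discount
        ``gamma`` in ``[0, 1)``; also the continuation probability of the
        repeated game.
    epsilon_floor, epsilon_amplitude
        Constants of the exploration schedule
        ``eps(t) = floor + amplitude / (1 + t)`` with ``t`` the game index.
    learning_rate
        Adam step size for the neural value function, or the fixed step
        for tabular updates when ``tabular_visit_decay`` is off.
    hidden_sizes
        Widths of the MLP hidden layers.
    update_mode
        ``"online"`` (one gradient step per period on the current
        transition) or ``"replay"`` (push to a small ring buffer, train on
        a sampled minibatch each period).
    terminal_bootstrap
        If True (default) the TD target bootstraps through the last period
        of a game, consistent with reading ``gamma`` as a continuation
        probability; if False the final-period target is the bare reward.
    target_sync
        If set, a frozen copy of the network supplies bootstrap values and
        is refreshed every ``target_sync`` updates.  Off by default: the
        state space is tiny and the plain online rule is the model.
    tabular_visit_decay
        If True, tabular cells use the Robbins-Monro style step
        ``visit_decay_offset / (visit_decay_offset + n_visits(cell))``
        instead of the fixed ``learning_rate``.
    """

    discount: float = 0.9
    epsilon_floor: float = 0.001
    epsilon_amplitude: float = 0.25
    learning_rate: float = 0.01
    hidden_sizes: tuple[int, ...] = (16, 16)
    update_mode: str = "online"
    replay_capacity: int = 200
    batch_size: int = 16
    terminal_bootstrap: bool = True
    target_sync: int | None = None
    tabular_visit_decay: bool = False
    visit_decay_offset: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount < 1.0:
            raise ValueError(f"discount must lie in [0, 1), got {self.discount}")
        if self.epsilon_floor < 0 or self.epsilon_amplitude < 0:
            raise ValueError("epsilon constants must be non-negative")
        if self.epsilon_floor + self.epsilon_amplitude > 1.0:
            raise ValueError("epsilon schedule must stay within [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.update_mode not in ("online", "replay"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")


def epsilon_schedule(game_index: int, cfg: LearningConfig) -> float:
    """Exploration probability for game ``t``: ``floor + amplitude / (1 + t)``.

    ``t`` counts *games* (0-based) and is constant within a game, so early
    games mix in roughly 25% random moves while from the middle of the
    session onwards the agents act almost purely greedily (the schedule
    decays to the floor, 0.001 by default).
    """
    if game_index < 0:
        raise ValueError(f"game_index must be >= 0, got {game_index}")
    return cfg.epsilon_floor + cfg.epsilon_amplitude / (1.0 + game_index)


def select_actions(
    q_values: np.ndarray, epsilon: float, rng: np.random.Generator
) -> np.ndarray:
    """Epsilon-greedy choice for a population of agents.

    ``q_values`` has shape ``(A, 2)`` with column 0 = defect, column 1 =
    cooperate.  With probability ``epsilon`` an agent plays uniformly at
    random; otherwise it plays the argmax, with exact ties broken
    uniformly at random (the tie regime is precisely where near-equal
    action values should not be resolved by an arbitrary systematic rule).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    q = np.asarray(q_values, dtype=np.float64)
    if np.isnan(q).any():
        raise AgentStateError("NaN Q-values encountered during action selection")
    greedy = (q[:, ACTION_C] > q[:, ACTION_D]).astype(np.int64)
    ties = q[:, ACTION_C] == q[:, ACTION_D]
    if ties.any():
        greedy[ties] = rng.integers(0, 2, size=int(ties.sum()))
    explore = rng.random(q.shape[0]) < epsilon
    if explore.any():
        randoms = rng.integers(0, 2, size=q.shape[0])
        greedy = np.where(explore, randoms, greedy)
    return greedy


def select_action(q: QPair, epsilon: float, rng: np.random.Generator) -> int:
    """Single-agent epsilon-greedy choice; returns 1 (C) or 0 (D)."""
    qv = np.array([[q.q_defect, q.q_cooperate]], dtype=np.float64)
    return int(select_actions(qv, epsilon, rng)[0])


def td_target(transition: Transition, vf: "ValueFunction", discount: float) -> float:
    """One-step bootstrapped target ``r + gamma * max(QC', QD')``."""
    nxt = vf.evaluate(transition.next_observation)
    return float(transition.reward) + discount * max(nxt.q_cooperate, nxt.q_defect)


class ValueFunction:
    """Contract shared by the tabular and neural value functions.

    ``evaluate`` is deterministic given the internal parameters; ``update``
    with a zero learning rate leaves ``evaluate`` unchanged.  Population
    methods (``q_values`` / ``learn_step``) act on all agents at once with
    one observation/transition per agent.
    """

    n_agents: int

    # -- single-agent contract (agent 0) ---------------------------------
    def evaluate(self, obs: Observation) -> QPair:
        raise NotImplementedError

    def update(self, batch: Sequence[Transition], cfg: LearningConfig) -> "ValueFunction":
        raise NotImplementedError

    # -- population interface --------------------------------------------
    def q_values(self, prev_actions: np.ndarray, fractions: np.ndarray) -> np.ndarray:
        """Shape ``(A, 2)`` action values, one row per agent."""
        raise NotImplementedError

    def learn_step(
        self,
        prev_actions: np.ndarray,
        fractions: np.ndarray,
        actions: np.ndarray,
        rewards: np.ndarray,
        next_prev_actions: np.ndarray,
        next_fractions: np.ndarray,
        cfg: LearningConfig,
        terminal: bool = False,
    ) -> None:
        """One TD update per agent from that agent's own transition."""
        raise NotImplementedError


class TabularQ(ValueFunction):
    """Exact Q-table on the observation grid ``{0,1} x {k/(N-1)}``.

    The table has shape ``(n_agents, 2, N, 2)`` indexed by
    ``(agent, previous action, others' cooperator count k, action)``.
    Updates follow the Watkins stochastic fixed-point iteration
    ``Q <- Q + eta * (target - Q)``.
    """

    def __init__(self, n_players: int, n_agents: int = 1, init: float = 0.0):
        self.n_players = n_players
        self.n_agents = n_agents
        self.table = np.full((n_agents, 2, n_players, 2), float(init))
        self.visits = np.zeros((n_agents, 2, n_players, 2), dtype=np.int64)

    def _k(self, fractions: np.ndarray) -> np.ndarray:
        raw = np.asarray(fractions, dtype=np.float64) * (self.n_players - 1)
        k = np.rint(raw).astype(np.int64)
        if np.any(np.abs(raw - k) > 1e-9) or np.any((k < 0) | (k > self.n_players - 1)):
            raise ProfileError(
                "observation fraction off the k/(N-1) grid — group size mismatch?"
            )
        return k

    def evaluate(self, obs: Observation) -> QPair:
        k = int(self._k(np.array([obs.others_coop_fraction]))[0])
        cell = self.table[0, int(obs.prev_action), k]
        return QPair(float(cell[ACTION_C]), float(cell[ACTION_D]))

    def q_values(self, prev_actions, fractions) -> np.ndarray:
        k = self._k(fractions)
        a = np.asarray(prev_actions, dtype=np.int64)
        return self.table[np.arange(self.n_agents), a, k, :]

    def _step_sizes(self, idx, cfg: LearningConfig) -> np.ndarray:
        if not cfg.tabular_visit_decay:
            return np.full(idx[0].shape, cfg.learning_rate)
        self.visits[idx] += 1
        c = cfg.visit_decay_offset
        return c / (c + self.visits[idx])

    def learn_step(
        self, prev_actions, fractions, actions, rewards,
        next_prev_actions, next_fractions, cfg, terminal=False,
    ) -> None:
        agents = np.arange(self.n_agents)
        k = self._k(fractions)
        a_prev = np.asarray(prev_actions, dtype=np.int64)
        acts = np.asarray(actions, dtype=np.int64)
        if terminal:
            targets = np.asarray(rewards, dtype=np.float64)
        else:
            k_next = self._k(next_fractions)
            a_next = np.asarray(next_prev_actions, dtype=np.int64)
            next_max = self.table[agents, a_next, k_next, :].max(axis=-1)
            targets = np.asarray(rewards, dtype=np.float64) + cfg.discount * next_max
        idx = (agents, a_prev, k, acts)
        eta = self._step_sizes(idx, cfg)
        self.table[idx] += eta * (targets - self.table[idx])

    def update(self, batch: Sequence[Transition], cfg: LearningConfig) -> "TabularQ":
        for tr in batch:
            self.learn_step(
                np.array([tr.observation.prev_action]),
                np.array([tr.observation.others_coop_fraction]),
                np.array([tr.action]),
                np.array([tr.reward]),
                np.array([tr.next_observation.prev_action]),
                np.array([tr.next_observation.others_coop_fraction]),
                cfg,
            )
        return self


class NeuralQ(ValueFunction):
    """Population of independent small MLP value functions.

    Architecture per agent: 2 inputs (previous action as 0/1, others'
    cooperation fraction as a real) -> ReLU hidden layers -> 2 linear
    outputs (QD, QC).  Parameters are stored stacked along a leading agent
    axis so a whole group trains with a handful of batched matmuls per
    period; agents never share parameters or gradients.

    Training minimizes the squared error between the evaluated Q of the
    *taken* action and a frozen TD target, one Adam step per call.
    """

    BETA1, BETA2, EPS = 0.9, 0.999, 1e-8

    def __init__(
        self,
        n_agents: int = 1,
        hidden_sizes: Sequence[int] = (16, 16),
        rng: np.random.Generator | None = None,
        target_sync: int | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        self.n_agents = n_agents
        self.hidden_sizes = tuple(hidden_sizes)
        sizes = (2, *self.hidden_sizes, 2)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU stack
            self.weights.append(rng.normal(0.0, scale, (n_agents, fan_in, fan_out)))
            self.biases.append(np.zeros((n_agents, 1, fan_out)))
        self._adam_m = [np.zeros_like(p) for p in self.weights + self.biases]
        self._adam_v = [np.zeros_like(p) for p in self.weights + self.biases]
        self._adam_t = 0
        self.target_sync = target_sync
        self._target_params: tuple[list[np.ndarray], list[np.ndarray]] | None = None
        self._updates_since_sync = 0

    # -- forward ----------------------------------------------------------
    def _forward(self, x: np.ndarray, params=None):
        """x: (A, B, 2) -> (q (A, B, 2), cache of pre/post activations)."""
        weights, biases = params if params is not None else (self.weights, self.biases)
        h = x
        cache = [x]
        for i, (w, b) in enumerate(zip(weights, biases)):
            z = h @ w + b
            if i < len(weights) - 1:
                h = np.maximum(z, 0.0)
                cache.append(h)
            else:
                h = z
        return h, cache

    @staticmethod
    def _features(prev_actions, fractions) -> np.ndarray:
        a = np.asarray(prev_actions, dtype=np.float64)
        p = np.asarray(fractions, dtype=np.float64)
        return np.stack([a, p], axis=-1)

    def q_values(self, prev_actions, fractions) -> np.ndarray:
        x = self._features(prev_actions, fractions)[:, None, :]  # (A, 1, 2)
        q, _ = self._forward(x)
        return q[:, 0, :]

    def evaluate(self, obs: Observation) -> QPair:
        x = np.array([[[float(obs.prev_action), obs.others_coop_fraction]]])
        q, _ = self._forward(x[: 1] if self.n_agents == 1 else
                             np.repeat(x, self.n_agents, axis=0))
        return QPair(float(q[0, 0, ACTION_C]), float(q[0, 0, ACTION_D]))

    # -- backward ---------------------------------------------------------
    def regress_step(
        self,
        prev_actions: np.ndarray,
        fractions: np.ndarray,
        actions: np.ndarray,
        targets: np.ndarray,
        learning_rate: float,
    ) -> float:
        """One Adam step of ``(Q(s, a) - target)^2`` on given targets.

        Inputs are ``(A, B)`` arrays (one minibatch of size B per agent);
        1-D arrays of length A are treated as one sample per agent
        (B = 1).  Returns the mean squared error over the batch before the
        step.  This is the supervised core that ``learn_step`` drives with
        TD targets; it is also usable directly as a plain regression onto
        known values.
        """
        prev = _per_agent_2d(prev_actions, np.float64)
        frac = _per_agent_2d(fractions, np.float64)
        acts = _per_agent_2d(actions, np.int64)
        y = _per_agent_2d(targets, np.float64)
        A, B = prev.shape
        x = np.stack([prev, frac], axis=-1)  # (A, B, 2)
        q, cache = self._forward(x)
        taken = np.take_along_axis(q, acts[..., None], axis=-1)[..., 0]
        err = taken - y
        with np.errstate(over="ignore"):
            mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise TrainingDivergenceError(
                f"non-finite training loss (hidden={self.hidden_sizes}, "
                f"lr={learning_rate}, step={self._adam_t})"
            )
        if learning_rate == 0.0:
            return mse
        # gradient of mean over batch; only the taken action's head receives error
        dout = np.zeros_like(q)
        np.put_along_axis(dout, acts[..., None], (2.0 * err / B)[..., None], axis=-1)
        grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
        delta = dout
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache[i]
            grads_w[i] = np.swapaxes(h_in, 1, 2) @ delta
            grads_b[i] = delta.sum(axis=1, keepdims=True)
            if i > 0:
                delta = (delta @ np.swapaxes(self.weights[i], 1, 2)) * (cache[i] > 0.0)
        self._adam_t += 1
        t = self._adam_t
        params = self.weights + self.biases
        grads = grads_w + grads_b
        for j, (p, g) in enumerate(zip(params, grads)):
            m = self._adam_m[j]
            v = self._adam_v[j]
            m *= self.BETA1
            m += (1 - self.BETA1) * g
            v *= self.BETA2
            v += (1 - self.BETA2) * g**2
            mhat = m / (1 - self.BETA1**t)
            vhat = v / (1 - self.BETA2**t)
            p -= learning_rate * mhat / (np.sqrt(vhat) + self.EPS)
        if not all(np.isfinite(p).all() for p in params):
            raise TrainingDivergenceError(
                f"non-finite MLP parameters (hidden={self.hidden_sizes}, "
                f"lr={learning_rate}, step={t})"
            )
        return mse

    def _bootstrap_params(self):
        if self.target_sync is None or self._target_params is None:
            return None
        return self._target_params

    def _maybe_sync_target(self) -> None:
        if self.target_sync is None:
            return
        if self._target_params is None or self._updates_since_sync >= self.target_sync:
            self._target_params = (
                [w.copy() for w in self.weights],
                [b.copy() for b in self.biases],
            )
            self._updates_since_sync = 0
        self._updates_since_sync += 1

    def learn_step(
        self, prev_actions, fractions, actions, rewards,
        next_prev_actions, next_fractions, cfg, terminal=False,
    ) -> None:
        rewards = _per_agent_2d(rewards, np.float64)
        if terminal:
            targets = rewards
        else:
            self._maybe_sync_target()
            xn = self._features(
                _per_agent_2d(next_prev_actions, np.float64),
                _per_agent_2d(next_fractions, np.float64),
            )
            qn, _ = self._forward(xn, params=self._bootstrap_params())
            targets = rewards + cfg.discount * qn.max(axis=-1)
        self.regress_step(
            _per_agent_2d(prev_actions, np.float64),
            _per_agent_2d(fractions, np.float64),
            _per_agent_2d(actions, np.int64), targets, cfg.learning_rate,
        )

    def update(self, batch: Sequence[Transition], cfg: LearningConfig) -> "NeuralQ":
        """Single-agent contract update: one gradient step on the batch."""
        if self.n_agents != 1:
            raise ValueError("the Transition-batch interface is single-agent")
        if not batch:
            raise ValueError("batch must be nonempty")
        prev = np.array([[tr.observation.prev_action for tr in batch]], dtype=float)
        frac = np.array([[tr.observation.others_coop_fraction for tr in batch]])
        acts = np.array([[tr.action for tr in batch]])
        rew = np.array([[tr.reward for tr in batch]])
        nprev = np.array([[tr.next_observation.prev_action for tr in batch]], dtype=float)
        nfrac = np.array([[tr.next_observation.others_coop_fraction for tr in batch]])
        self.learn_step(prev, frac, acts, rew, nprev, nfrac, cfg)
        return self

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        """Persist parameters to a flat ``.npz`` array container."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        np.savez(path, hidden=np.array(self.hidden_sizes), **arrays)

    @classmethod
    def load(cls, path) -> "NeuralQ":
        with np.load(path) as data:
            hidden = tuple(int(h) for h in data["hidden"])
            n_agents = data["w0"].shape[0]
            vf = cls(n_agents=n_agents, hidden_sizes=hidden,
                     rng=np.random.default_rng(0))
            vf.weights = [data[f"w{i}"].copy() for i in range(len(vf.weights))]
            vf.biases = [data[f"b{i}"].copy() for i in range(len(vf.biases))]
        return vf


class ReplayBuffer:
    """Per-agent ring buffers of transitions, stored as flat arrays."""

    FIELDS = 6  # prev_a, frac, action, reward, next_a, next_frac

    def __init__(self, n_agents: int, capacity: int):
        self.n_agents = n_agents
        self.capacity = capacity
        self.data = np.zeros((n_agents, capacity, self.FIELDS))
        self.size = 0
        self._pos = 0

    def push(self, prev_a, frac, actions, rewards, next_a, next_frac) -> None:
        self.data[:, self._pos, :] = np.stack(
            [prev_a, frac, actions, rewards, next_a, next_frac], axis=-1
        )
        self._pos = (self._pos + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, size=(self.n_agents, batch_size))
        batch = np.take_along_axis(self.data, idx[..., None], axis=1)
        prev_a, frac, acts, rew, next_a, next_frac = np.moveaxis(batch, -1, 0)
        return prev_a, frac, acts.astype(np.int64), rew, next_a, next_frac


def train_vs_random(
    vf: ValueFunction,
    game_cfg: GameConfig,
    learn_cfg: LearningConfig,
    n_updates: int,
    rng: np.random.Generator,
    behaviour: str = "uniform",
) -> ValueFunction:
    """Train one focal agent against i.i.d. coin-flip opponents.

    Every period the ``N - 1`` opponents cooperate independently with
    probability 1/2, which makes the environment a fixed Markov chain and
    the closed-form values of :mod:`pggq.closed_form` the exact solution.
    The focal behaviour policy is ``"uniform"`` (pure random, maximal
    state coverage — Q-learning is off-policy so this still converges to
    the optimal values) or ``"greedy"`` (epsilon-greedy at the schedule
    floor).  Used for convergence checks and as a learning benchmark.
    """
    if vf.n_agents != 1:
        raise ValueError("train_vs_random drives a single focal agent")
    n = game_cfg.n_players
    alpha = game_cfg.mpcr
    c = game_cfg.contribution_cost
    chunk = 4096
    # pre-draw opponent counts and focal exploration in chunks; the update
    # itself is sequential because targets bootstrap on the evolving table
    k_prev = int(rng.integers(0, n))
    a_prev = int(rng.integers(0, 2))
    done = 0
    eps_floor = learn_cfg.epsilon_floor
    while done < n_updates:
        m = min(chunk, n_updates - done)
        k_draws = rng.binomial(n - 1, 0.5, size=m)
        u_act = rng.integers(0, 2, size=m)
        u_explore = rng.random(m)
        for i in range(m):
            if behaviour == "uniform":
                a = int(u_act[i])
            else:
                q = vf.q_values(np.array([a_prev]), np.array([k_prev / (n - 1)]))[0]
                a = int(q[ACTION_C] > q[ACTION_D])
                if u_explore[i] < eps_floor:
                    a = int(u_act[i])
            k_now = int(k_draws[i])
            r = c * (alpha * (k_now + a) - a)
            vf.learn_step(
                np.array([a_prev]), np.array([k_prev / (n - 1)]),
                np.array([a]), np.array([r]),
                np.array([a]), np.array([k_now / (n - 1)]),
                learn_cfg,
            )
            a_prev, k_prev = a, k_now
        done += m
    return vf
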