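"""Analytic Q-values against randomizing opponents and the learning difficulty.

When every opponent cooperates independently with probability 1/2, the
environment seen by a focal agent is a fixed Markov chain and the Bellman
recursion can be solved in closed form.  Expected one-period gains are

    r_D = alpha * (N - 1) / 2
    r_C = r_D - (1 - alpha)

(the pot share from the others is the same either way; cooperating adds
``alpha - 1`` net).  Neither the rewards nor the transition kernel depend
on the current observation, so the optimal values are state-independent:
for ``alpha < 1`` the greedy continuation is defection and

    QD = r_D / (1 - gamma),        QC = r_C + gamma * QD.

The *difficulty of learning* is the relative value gap

    1 - QC / QD = 2 (1 - alpha) (1 - gamma) / (alpha (N - 1)),

strictly decreasing in N, alpha and gamma on the dilemma range.  Near 0
the two actions are almost indistinguishable to a bounded-accuracy
learner, which drifts toward ~50% cooperation — the mechanism by which
larger groups and higher per-capita returns sustain cooperation.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .agents import QPair

__all__ = [
    "difficulty",
    "expected_game_length",
    "landscape",
    "random_opponent_q",
    "value_iteration_q",
]


def _check_params(n_players: int, mpcr: float, gamma: float) -> None:
    if n_players < 2:
        raise ValueError(f"n_players must be >= 2, got {n_players}")
    if mpcr <= 0:
        raise ValueError(f"mpcr must be positive, got {mpcr}")
    if not 0.0 <= gamma < 1.0:
        raise ValueError(
            f"discount {gamma} outside [0, 1): the value series diverges"
        )


def random_opponent_q(n_players: int, mpcr: float, gamma: float) -> QPair:
    """Fixed-point Q-values when opponents are fair coin flippers.

    For ``mpcr < 1`` (defection dominant) returns
    ``QD = r_D / (1 - gamma)``, ``QC = r_C + gamma * QD``; for
    ``mpcr >= 1`` the greedy branch flips to cooperation (computed
    accordingly, with a warning: outside the dilemma range).
    """
    _check_params(n_players, mpcr, gamma)
    r_d = mpcr * (n_players - 1) / 2.0
    r_c = r_d - (1.0 - mpcr)
    if mpcr < 1.0:
        q_d = r_d / (1.0 - gamma)
        q_c = r_c + gamma * q_d
    else:
        if mpcr > 1.0:
            warnings.warn(
                f"mpcr={mpcr} >= 1: cooperation is dominant, no dilemma",
                stacklevel=2,
            )
        q_c = r_c / (1.0 - gamma)
        q_d = r_d + gamma * q_c
    return QPair(q_cooperate=q_c, q_defect=q_d)


def value_iteration_q(
    n_players: int,
    mpcr: float,
    gamma: float,
    tol: float = 1e-13,
    max_iter: int = 100_000,
) -> QPair:
    """Brute-force Bellman iteration on the full observation grid.

    Solves the same random-opponent problem as :func:`random_opponent_q`
    but numerically, sweeping ``Q(s, a)`` over the explicit state space
    ``{0,1} x {k/(N-1)}`` with the exact binomial transition kernel until
    the sup-norm change falls below ``tol``.  Serves as the independent
    cross-check that the closed form is the true fixed point; the returned
    pair is the (state-independent) converged value, taken at the
    all-defect state.
    """
    _check_params(n_players, mpcr, gamma)
    n = n_players
    k = np.arange(n)  # others' cooperator count
    p_k = stats.binom.pmf(k, n - 1, 0.5)
    # expected reward of each action given the *next* round's draw:
    # r(a) = alpha * (k' + a) - a averaged over k' ~ Binom(n-1, 1/2)
    r = np.array([mpcr * (n - 1) / 2.0 + a * (mpcr - 1.0) for a in (0, 1)])
    q = np.zeros((2, n, 2))  # (prev action, k, action)
    for _ in range(max_iter):
        # landing state after action a is (a, k'), k' binomial
        cont = np.tensordot(p_k, q.max(axis=-1), axes=([0], [1]))  # (2,) by action
        q_new = np.broadcast_to(r + gamma * cont, (2, n, 2)).copy()
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    else:
        raise RuntimeError("value iteration failed to converge")
    return QPair(q_cooperate=float(q[0, 0, 1]), q_defect=float(q[0, 0, 0]))


def difficulty(q: QPair) -> float:
    """Learning difficulty ``1 - QC / QD`` of a value pair.

    Zero means the actions are indistinguishable in value (no learning
    problem); values near 1 mean defection is unambiguously superior.
    Undefined at ``QD = 0`` (which occurs only at ``alpha = 0``).
    """
    if q.q_defect == 0.0:
        raise ZeroDivisionError("difficulty undefined when QD = 0")
    return 1.0 - q.q_cooperate / q.q_defect


def expected_game_length(gamma: float) -> float:
    """Mean number of periods, ``1 / (1 - gamma)``, when ``gamma`` is read
    as the per-period continuation probability of the repeated game."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma {gamma} outside [0, 1): infinite game")
    return 1.0 / (1.0 - gamma)


def landscape(n_values, mpcr_values, gamma_values) -> pd.DataFrame:
    """Closed-form (QC, QD, difficulty) over a parameter grid.

    Returns a tidy frame with columns ``N, alpha, gamma, QC, QD,
    difficulty`` suitable for CSV export.
    """
    rows = []
    for n, a, g in itertools.product(n_values, mpcr_values, gamma_values):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = random_opponent_q(int(n), float(a), float(g))
        rows.append(
            {"N": int(n), "alpha": float(a), "gamma": float(g),
             "QC": q.q_cooperate, "QD": q.q_defect, "difficulty": difficulty(q)}
        )
    return pd.DataFrame(rows)
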