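"""The N-person public goods stage game.

Each of the ``N`` players in a group chooses whether to contribute a unit
cost ``c = 1`` to a common pot (cooperate, ``g = 1``) or keep it (defect,
``g = 0``).  The pot is multiplied by ``b`` and shared equally, so a focal
player's one-period gain is

    r_i = -c * g_i + (b / N) * sum_j g_j = c * (-g_i + alpha * sum_j g_j),

where ``alpha = b / N`` is the marginal per capita return (MPCR): the
private return on one unit of own contribution.  A social dilemma exists
exactly when ``1/N < alpha < 1`` — contributing raises group income
(``b > c``) but lowers own income (``alpha < 1``), so defection is the
strictly dominant action while universal cooperation is efficient.

Agents never see the full action profile.  The information state fed to a
value function is the two-component observation
``(own previous action, cooperation fraction of the *other* N-1 players
in the previous round)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GameConfig",
    "Observation",
    "ProfileError",
    "immediate_gain",
    "observe",
    "observe_all",
    "others_coop_count",
    "payoff_spread",
]


class ProfileError(ValueError):
    """An action profile is inconsistent with the game configuration."""


@dataclass(frozen=True)
class GameConfig:
    """Stage-game parameters.

    Parameters
    ----------
    n_players
        Group size ``N >= 2`` (``N = 1`` would leave the others' cooperation
        fraction undefined).
    mpcr
        Marginal per capita return ``alpha = b / N``.
    contribution_cost
        Unit cost of cooperating, ``c``; fixed at 1 in the standard game.
    """

    n_players: int
    mpcr: float
    contribution_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise ValueError(f"n_players must be >= 2, got {self.n_players}")
        if self.mpcr < 0:
            raise ValueError(f"mpcr must be non-negative, got {self.mpcr}")
        if self.contribution_cost <= 0:
            raise ValueError("contribution_cost must be positive")

    @property
    def multiplier(self) -> float:
        """Pot multiplier ``b = alpha * N``."""
        return self.mpcr * self.n_players

    @property
    def is_dilemma(self) -> bool:
        """True iff ``1/N < alpha < 1``, the range where the dilemma exists.

        Configurations outside this range are legal (the game is still
        well defined) but carry no social dilemma: for ``alpha >= 1``
        cooperation is individually profitable, for ``alpha <= 1/N`` it
        does not even pay for the group.
        """
        return 1.0 / self.n_players < self.mpcr < 1.0


class Observation(NamedTuple):
    """The two-component information state of a focal agent.

    ``others_coop_fraction`` always excludes the focal agent's own action
    and therefore lies on the exact grid ``k / (N - 1)``, ``k = 0 .. N-1``.
    """

    prev_action: int
    others_coop_fraction: float


def _validate_profile(contributions: np.ndarray, cfg: GameConfig) -> np.ndarray:
    g = np.asarray(contributions)
    if g.shape != (cfg.n_players,):
        raise ProfileError(
            f"profile has shape {g.shape}, expected ({cfg.n_players},)"
        )
    if not np.isin(g, (0, 1)).all():
        raise ProfileError("contributions must be 0 (defect) or 1 (cooperate)")
    return g.astype(np.int64)


def immediate_gain(contributions, cfg: GameConfig) -> np.ndarray:
    """One-period payoff vector ``r_i = c * (-g_i + alpha * sum_j g_j)``.

    The pot share ``(b/N) * sum_j g_j`` is written through the MPCR as
    ``alpha * sum_j g_j``; the focal agent's own contribution is included
    in the pot.  Total payoff across the group equals
    ``(alpha * N - 1) * c * (#cooperators)``.
    """
    g = _validate_profile(contributions, cfg)
    pot_share = cfg.mpcr * g.sum()
    return cfg.contribution_cost * (pot_share - g).astype(np.float64)


def observe(agent_index: int, contributions, cfg: GameConfig) -> Observation:
    """The focal agent's observation of a completed round.

    Returns ``(g_i, (sum_j g_j - g_i) / (N - 1))`` — own action and the
    cooperation fraction among the *other* players only.
    """
    g = _validate_profile(contributions, cfg)
    if not 0 <= agent_index < cfg.n_players:
        raise IndexError(f"agent_index {agent_index} out of range")
    own = int(g[agent_index])
    frac = (int(g.sum()) - own) / (cfg.n_players - 1)
    return Observation(own, frac)


def observe_all(contributions, cfg: GameConfig) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`observe` for every agent at once.

    Returns ``(prev_actions, others_coop_fractions)`` as arrays of length N.
    """
    g = _validate_profile(contributions, cfg)
    frac = (g.sum() - g) / (cfg.n_players - 1)
    return g, frac.astype(np.float64)


def others_coop_count(obs: Observation, cfg: GameConfig) -> int:
    """Recover the integer cooperator count ``k`` from the exact grid fraction.

    Observations produced by the simulator always satisfy
    ``others_coop_fraction = k / (N - 1)`` exactly; anything else signals a
    group-size mismatch and is rejected.
    """
    raw = obs.others_coop_fraction * (cfg.n_players - 1)
    k = int(round(raw))
    if abs(raw - k) > 1e-9 or not 0 <= k <= cfg.n_players - 1:
        raise ProfileError(
            f"fraction {obs.others_coop_fraction} is not on the "
            f"k/(N-1) grid for N={cfg.n_players}"
        )
    return k


def payoff_spread(cfg: GameConfig) -> float:
    """Range of a focal payoff attributable to the others, ``alpha * (N - 1)``.

    With own action held fixed, the others' cooperator count ``k`` ranges
    over ``0 .. N-1`` and contributes ``alpha * k`` to the focal payoff, so
    the payoff spread driven by the environment is ``alpha * (N - 1)``.
    This grows linearly with the group size while the cost of cooperating
    stays at ``(1 - alpha)`` per round — the asymmetry behind the
    learning-difficulty analysis in :mod:`pggq.closed_form`.
    """
    return cfg.mpcr * (cfg.n_players - 1)
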