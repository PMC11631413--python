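"""The group-play protocol and parameter sweeps.

A *group* is ``N`` co-learning agents.  The group plays 30 consecutive
*games* of 20 *periods* each; agents learn in every period of every game,
but the first 10 games (200 periods) are discarded from analysis as the
learning phase.  Cooperation statistics are computed over the retained
window and then averaged across 30-50 independent replicate groups.

Exploration decays per game (not per period); at the start of each game
there is no previous round, so each agent's fictitious previous action is
drawn uniformly at random and the observed cooperation fraction is
computed from those draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import (
    LearningConfig,
    NeuralQ,
    ReplayBuffer,
    TabularQ,
    TrainingDivergenceError,
    epsilon_schedule,
    select_actions,
)
from .game import GameConfig

__all__ = [
    "AGENT_TYPES",
    "BudgetError",
    "ExperimentConfig",
    "GroupResult",
    "Summary",
    "group_seed",
    "run_experiment",
    "run_group",
    "summarize",
    "sweep",
    "trajectory_frame",
    "write_run",
]

AGENT_TYPES = ("neural", "tabular", "fixed_all_D", "fixed_all_C", "random")


class BudgetError(RuntimeError):
    """A sweep cell exceeds the configured compute budget."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Full protocol configuration for one experimental cell."""

    game: GameConfig
    learning: LearningConfig = field(default_factory=LearningConfig)
    n_games: int = 30
    n_periods: int = 20
    discard_games: int = 10
    n_groups: int = 30
    master_seed: int = 0
    agent_type: str = "neural"

    def __post_init__(self) -> None:
        if self.agent_type not in AGENT_TYPES:
            raise ValueError(
                f"agent_type must be one of {AGENT_TYPES}, got {self.agent_type!r}"
            )
        if not 0 <= self.discard_games < self.n_games:
            raise ValueError("discard_games must satisfy 0 <= discard < n_games")
        if self.n_groups < 1 or self.n_periods < 1:
            raise ValueError("n_groups and n_periods must be positive")

    @property
    def retained_periods(self) -> int:
        return (self.n_games - self.discard_games) * self.n_periods


@dataclass
class GroupResult:
    """Per-period cooperation record of one replicate group.

    ``coop_trajectory`` has shape ``(n_games, n_periods)`` and includes the
    discarded learning phase; the retained statistics cover games
    ``>= discard_games`` only.  A group whose training diverged is kept,
    flagged, with the failure message as diagnostics.
    """

    coop_trajectory: np.ndarray
    retained_mean: float
    retained_sd: float
    failed: bool = False
    failure: str | None = None


@dataclass(frozen=True)
class Summary:
    """Across-group summary of one experimental cell."""

    mean_coop: float
    sd_coop: float
    n_groups: int
    n_failed: int = 0


def group_seed(master_seed: int, cell: int, group: int) -> np.random.SeedSequence:
    """Counter-based per-group seed derivation.

    Uses an explicit spawn key ``(cell, group)`` so adding groups or sweep
    cells never perturbs the random stream of earlier ones.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(cell, group))


def _make_value_function(cfg: ExperimentConfig, rng: np.random.Generator):
    n = cfg.game.n_players
    if cfg.agent_type == "tabular":
        return TabularQ(n_players=n, n_agents=n)
    if cfg.agent_type == "neural":
        return NeuralQ(
            n_agents=n,
            hidden_sizes=cfg.learning.hidden_sizes,
            rng=rng,
            target_sync=cfg.learning.target_sync,
        )
    return None


def run_group(cfg: ExperimentConfig, seed) -> GroupResult:
    """Simulate one group through the full protocol.

    All agents act simultaneously each period; value functions are updated
    every period (online or from replay) including during the retained
    window, where the small exploration floor keeps behaviour almost but
    not exactly greedy.  Value functions are initialized fresh: groups are
    independent replicates with no cross-group transfer.
    """
    rng = np.random.default_rng(seed)
    n = cfg.game.n_players
    learn = cfg.agent_type in ("neural", "tabular")
    vf = _make_value_function(cfg, rng)
    buffer = None
    if learn and cfg.learning.update_mode == "replay":
        buffer = ReplayBuffer(n_agents=n, capacity=cfg.learning.replay_capacity)
    mpcr, cost = cfg.game.mpcr, cfg.game.contribution_cost
    traj = np.empty((cfg.n_games, cfg.n_periods))
    try:
        for g in range(cfg.n_games):
            eps = epsilon_schedule(g, cfg.learning) if learn else 0.0
            prev = rng.integers(0, 2, size=n)  # fictitious round before period 1
            for t in range(cfg.n_periods):
                prev_frac = (prev.sum() - prev) / (n - 1)
                if learn:
                    q = vf.q_values(prev, prev_frac)
                    acts = select_actions(q, eps, rng)
                elif cfg.agent_type == "random":
                    acts = rng.integers(0, 2, size=n)
                elif cfg.agent_type == "fixed_all_C":
                    acts = np.ones(n, dtype=np.int64)
                else:  # fixed_all_D
                    acts = np.zeros(n, dtype=np.int64)
                rewards = cost * (mpcr * acts.sum() - acts).astype(np.float64)
                next_frac = (acts.sum() - acts) / (n - 1)
                if learn:
                    terminal = (
                        t == cfg.n_periods - 1
                        and not cfg.learning.terminal_bootstrap
                    )
                    if buffer is None:
                        vf.learn_step(
                            prev, prev_frac, acts, rewards, acts, next_frac,
                            cfg.learning, terminal=terminal,
                        )
                    else:
                        buffer.push(prev, prev_frac, acts, rewards, acts, next_frac)
                        if buffer.size >= cfg.learning.batch_size:
                            pa, fr, ba, br, na, nf = buffer.sample(
                                cfg.learning.batch_size, rng
                            )
                            vf.learn_step(
                                pa, fr, ba, br, na, nf, cfg.learning,
                                terminal=terminal,
                            )
                traj[g, t] = acts.mean()
                prev = acts
    except TrainingDivergenceError as exc:
        return GroupResult(
            coop_trajectory=traj,
            retained_mean=float("nan"),
            retained_sd=float("nan"),
            failed=True,
            failure=str(exc),
        )
    retained = traj[cfg.discard_games:]
    sd = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
    return GroupResult(traj, float(retained.mean()), sd)


def summarize(groups: list[GroupResult], ddof: int = 1) -> Summary:
    """Across-group mean and standard deviation of retained cooperation.

    Uses the sample (``ddof=1``) convention by default; failed groups are
    counted and excluded from the statistics, never silently dropped.
    """
    if not groups:
        raise ValueError("summarize requires at least one group")
    means = np.array([g.retained_mean for g in groups if not g.failed])
    n_failed = sum(g.failed for g in groups)
    if means.size == 0:
        raise TrainingDivergenceError("all groups in the cell failed")
    sd = float(means.std(ddof=ddof)) if means.size > ddof else 0.0
    return Summary(float(means.mean()), sd, len(groups), n_failed)


def run_experiment(
    cfg: ExperimentConfig, cell: int = 0
) -> tuple[list[GroupResult], Summary]:
    """Run ``cfg.n_groups`` independent groups and summarize them."""
    groups = [
        run_group(cfg, group_seed(cfg.master_seed, cell, g))
        for g in range(cfg.n_groups)
    ]
    return groups, summarize(groups)


_AXES = {"N": "n_players", "alpha": "mpcr", "gamma": "discount"}


def _cell_config(base: ExperimentConfig, axis: str, value) -> ExperimentConfig:
    if axis == "N":
        game = dataclasses.replace(base.game, n_players=int(value))
        return dataclasses.replace(base, game=game)
    if axis == "alpha":
        game = dataclasses.replace(base.game, mpcr=float(value))
        return dataclasses.replace(base, game=game)
    if axis == "gamma":
        learning = dataclasses.replace(base.learning, discount=float(value))
        return dataclasses.replace(base, learning=learning)
    raise ValueError(f"axis must be one of {tuple(_AXES)}, got {axis!r}")


def sweep(
    axis: str,
    values,
    base: ExperimentConfig,
    budget: int = 10_000,
    force: bool = False,
    keep_groups: bool = False,
):
    """One experimental cell per value of ``axis`` in {"N", "alpha", "gamma"}.

    A resource guard refuses any cell with ``N * n_groups > budget`` unless
    ``force`` is set (large groups are expensive; reduce ``n_groups`` the
    way the large-N protocol does).  Per-cell, per-group seeds derive from
    the master seed by counter, so results are reproducible cell by cell.

    Returns a tidy summary frame with columns ``(axis, axis_value,
    mean_coop, sd_coop, n_groups, n_failed, seed)``; with ``keep_groups``
    also returns ``{value: [GroupResult, ...]}``.
    """
    rows = []
    all_groups: dict = {}
    for cell, value in enumerate(values):
        cfg = _cell_config(base, axis, value)
        load = cfg.game.n_players * cfg.n_groups
        if load > budget and not force:
            raise BudgetError(
                f"cell {axis}={value}: N * n_groups = {load} exceeds the "
                f"budget of {budget}; lower n_groups or pass force=True"
            )
        groups, summary = run_experiment(cfg, cell=cell)
        if keep_groups:
            all_groups[value] = groups
        rows.append(
            {
                "axis": axis,
                "axis_value": value,
                "mean_coop": summary.mean_coop,
                "sd_coop": summary.sd_coop,
                "n_groups": summary.n_groups,
                "n_failed": summary.n_failed,
                "seed": base.master_seed,
            }
        )
    frame = pd.DataFrame(rows)
    return (frame, all_groups) if keep_groups else frame


def trajectory_frame(groups: list[GroupResult], axis_value=None) -> pd.DataFrame:
    """Tidy per-period trajectories: (axis_value, group_id, game, period, coop)."""
    records = []
    for gid, gr in enumerate(groups):
        n_games, n_periods = gr.coop_trajectory.shape
        games, periods = np.divmod(np.arange(n_games * n_periods), n_periods)
        records.append(
            pd.DataFrame(
                {
                    "axis_value": axis_value,
                    "group_id": gid,
                    "game": games,
                    "period": periods,
                    "coop_fraction": gr.coop_trajectory.ravel(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def write_run(
    out_dir,
    summary: pd.DataFrame,
    cfg: ExperimentConfig,
    trajectories: pd.DataFrame | None = None,
) -> Path:
    """Write summary.csv, optional trajectory.csv, and a metadata sidecar.

    The metadata records the complete configuration plus library versions,
    enough to re-run the experiment exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    if trajectories is not None:
        trajectories.to_csv(out / "trajectory.csv", index=False)
    meta = {
        "config": dataclasses.asdict(cfg),
        "versions": {"pggq": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out
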