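"""Summary statistics for learning runs.

Per-episode metrics (steps, total reward, wall hits, reward per step),
trailing moving averages over a configurable window, cross-run pointwise
aggregation, wall-value means, and value-map maxima with their distance
to the nearest goal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridworld import GridWorld


@dataclass(frozen=True)
class EpisodeMetrics:
    episode: int
    steps: int
    total_reward: float
    wall_hits: int

    @property
    def reward_per_step(self) -> float:
        return self.total_reward / self.steps


@dataclass(frozen=True)
class ValueSummary:
    """Where a value map peaks and how far that is from a real goal."""

    value_map: np.ndarray
    max_value: float
    argmax: tuple[int, int]
    distance_to_nearest_goal: int


def episode_metrics(trace, episode: int = 0) -> EpisodeMetrics:
    """Collapse an episode trace to its counts.  Every action is a step,
    wall hits included; total reward sums signed rewards."""
    if trace.steps < 1:
        raise ValueError("empty episode trace")
    return EpisodeMetrics(
        episode=episode,
        steps=trace.steps,
        total_reward=trace.total_reward,
        wall_hits=trace.wall_hits,
    )


def moving_stats(series, window: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Trailing moving mean and population SD: at episode e the window
    covers episodes max(1, e - window + 1) .. e (head truncated)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    rolling = s.rolling(window, min_periods=1)
    return rolling.mean().to_numpy(), rolling.std(ddof=0).to_numpy()


def aggregate_runs(per_run_series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise cross-run mean, population SD and sample count.

    Ragged tails (runs that stop early, e.g. under a global step budget)
    are excluded pointwise; the per-point n records how many runs remain.
    """
    series = [np.asarray(s, dtype=float) for s in per_run_series]
    if not series:
        raise ValueError("no runs to aggregate")
    length = max(len(s) for s in series)
    stacked = np.full((len(series), length), np.nan)
    for i, s in enumerate(series):
        stacked[i, : len(s)] = s
    n = np.sum(~np.isnan(stacked), axis=0)
    mean = np.nanmean(stacked, axis=0)
    sd = np.where(n > 0, np.nanstd(stacked, axis=0), np.nan)
    return mean, sd, n


def wall_value_mean(value_map: np.ndarray, world: GridWorld,
                    include_border: bool = True) -> float:
    """Mean of the value map over impassable squares (border ring included
    by default)."""
    value_map = np.asarray(value_map)
    if value_map.shape != (world.width, world.height):
        raise ValueError("value map and world dimensions disagree")
    mask = ~world.passable
    if not include_border:
        mask = mask.copy()
        mask[0, :] = mask[-1, :] = False
        mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        raise ValueError("world has no impassable squares under this mask")
    return float(value_map[mask].mean())


def value_argmax(value_map: np.ndarray, world: GridWorld) -> ValueSummary:
    """Global maximum over all squares (walls included); ties resolve to
    the smallest x, then smallest y.  Distance is Manhattan steps to the
    nearest goal."""
    value_map = np.asarray(value_map)
    flat = int(np.argmax(value_map))  # C-order: first max = smallest x, then y
    x = flat // value_map.shape[1] + 1
    y = flat % value_map.shape[1] + 1
    dist = min(abs(x - gx) + abs(y - gy) for gx, gy in world.goals)
    return ValueSummary(
        value_map=value_map,
        max_value=float(value_map[x - 1, y - 1]),
        argmax=(x, y),
        distance_to_nearest_goal=int(dist),
    )


def snapshot_value_map(agent, world: GridWorld) -> np.ndarray:
    """The agent's current value surface on every square: d1 - d2 for the
    basis learner, v_s for tabular SARSA, v_r - v_p for MaxPain."""
    return agent.value_map(world)


def radial_profile(value_map: np.ndarray, center: tuple[int, int],
                   max_radius: int | None = None) -> np.ndarray:
    """Ring-averaged value profile: mean value over squares whose rounded
    Euclidean distance from ``center`` equals each integer radius."""
    value_map = np.asarray(value_map)
    w, h = value_map.shape
    cx, cy = center
    xs = np.arange(1, w + 1)[:, None]
    ys = np.arange(1, h + 1)[None, :]
    dist = np.rint(np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)).astype(int)
    top = dist.max() if max_radius is None else max_radius
    return np.array([
        value_map[dist == r].mean() if (dist == r).any() else np.nan
        for r in range(top + 1)
    ])


# ---------------------------------------------------------------------------
# Tabular serialization helpers
# ---------------------------------------------------------------------------


def episodes_frame(results) -> pd.DataFrame:
    """Stack per-run episode metrics into one long DataFrame."""
    frames = []
    for res in results:
        df = res.episodes.copy()
        df.insert(0, "run", res.run_index)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_value_map_csv(value_map: np.ndarray, path) -> None:
    """20x20 CSV grid, rows = y from top (printed like the arena)."""
    grid = np.asarray(value_map).T[::-1]  # (y rows, x cols), top row = max y
    np.savetxt(path, grid, delimiter=",")


def read_value_map_csv(path) -> np.ndarray:
    grid = np.loadtxt(path, delimiter=",")
    return grid[::-1].T
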