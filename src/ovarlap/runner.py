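"""Softmax policy, the step/episode loop, and the experiment protocols.

Three protocols mirror the study design:

* painful navigation — 50 runs x 500 episodes per agent on a corridor
  maze with painful walls (wall hits cost -1), value-map snapshots at
  episodes 5/30/150/500;
* relearning — the same task, with the wall penalty switched off at a
  configured episode, tracking the mean wall value per episode;
* disturbed valuation — the basis-network learner alone on a painless
  four-goal arena for a fixed global budget of 40,000 steps per run,
  under the 2x2 design {intact, impaired} x {unnoised, noised}.

All randomness flows from one master seed through named substreams
(policy, basis widths, basis noise, tie-breaking, start randomization),
so a (config, seed) pair reproduces a run bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .agents import OVaRLAPAgent, OVaRLAPParams
from .basis import BasisSpec, build_basis
from .baselines import MaxPainAgent, TabularAgent
from .gridworld import FIXTURES, GridWorld

AGENT_KINDS = ("ovarlap", "tabular", "maxpain")
_AGENT_CODE = {kind: i for i, kind in enumerate(AGENT_KINDS)}

DEFAULT_TAU = 0.5
DEFAULT_SNAPSHOTS = (5, 30, 150, 500)
EPISODE_STEP_CAP = 100_000


@dataclass(frozen=True)
class PolicyParams:
    tau: float = DEFAULT_TAU

    def validate(self) -> None:
        if self.tau <= 0:
            raise ValueError("softmax temperature tau must be > 0")


def softmax_probabilities(values, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Boltzmann distribution over afterstate values; numerically stable."""
    if tau <= 0:
        raise ValueError("softmax temperature tau must be > 0")
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite action values")
    z = v / tau
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def select_action(values, tau: float, rng: np.random.Generator) -> int:
    """Sample an action index from the softmax over the four values."""
    p = softmax_probabilities(values, tau)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(p), u, side="right"))
    return min(idx, len(p) - 1)


@dataclass
class EpisodeTrace:
    start: tuple[int, int]
    steps: int = 0
    total_reward: float = 0.0
    wall_hits: int = 0
    truncated: bool = False
    transitions: list | None = None


def run_episode(world: GridWorld, agent, rng: np.random.Generator,
                tau: float = DEFAULT_TAU, step_cap: int = EPISODE_STEP_CAP,
                start: tuple[int, int] | None = None,
                record_transitions: bool = True) -> EpisodeTrace:
    """One select-act-observe-bootstrap-update episode (SARSA ordering).

    Ends on goal entry or after ``step_cap`` steps (flagged as truncated,
    not raised).  Wall-hit steps consume time and update like any step.
    The agent is updated in place.
    """
    s = world.start if start is None else start
    trace = EpisodeTrace(start=s, transitions=[] if record_transitions else None)
    a = select_action(agent.action_values(world, s), tau, rng)
    while True:
        tr = world.step(s, a)
        trace.steps += 1
        trace.total_reward += tr.reward
        trace.wall_hits += tr.wall_hit
        if record_transitions:
            trace.transitions.append(tr)
        if tr.terminal:
            agent.update(world, s, a, tr, None)
            return trace
        a_next = select_action(agent.action_values(world, tr.next_state), tau, rng)
        agent.update(world, s, a, tr, a_next)
        s, a = tr.next_state, a_next
        if trace.steps >= step_cap:
            trace.truncated = True
            return trace


# ---------------------------------------------------------------------------
# Agents from per-run streams
# ---------------------------------------------------------------------------


def _run_seed_sequence(master_seed: int, agent_kind: str, run_index: int):
    return np.random.SeedSequence([int(master_seed), _AGENT_CODE[agent_kind],
                                   int(run_index)])


def make_agent(kind: str, world: GridWorld, *, basis_seed: int = 0,
               theta: float = 1.0, alpha: float = 0.1, alpha2: float | None = None,
               gamma: float = 0.95, gamma_p: float = 0.5,
               noise_strength: float = 0.0, noise_fraction: float = 0.0,
               tie_rng: np.random.Generator | None = None):
    """Instantiate an agent by kind with the study's default parameters."""
    if kind == "ovarlap":
        spec = BasisSpec(theta=theta, width=world.width, height=world.height,
                         noise_strength=noise_strength,
                         noise_fraction=noise_fraction, seed=basis_seed)
        params = OVaRLAPParams(alpha1=alpha,
                               alpha2=alpha if alpha2 is None else alpha2,
                               gamma=gamma)
        return OVaRLAPAgent(build_basis(spec), params)
    if kind == "tabular":
        return TabularAgent(alpha=alpha, gamma=gamma,
                            shape=(world.width, world.height))
    if kind == "maxpain":
        return MaxPainAgent(alpha_r=alpha, alpha_p=alpha, gamma_r=gamma,
                            gamma_p=gamma_p, shape=(world.width, world.height),
                            rng=tie_rng)
    raise ValueError(f"unknown agent kind {kind!r}")


@dataclass
class RunResult:
    agent_kind: str
    run_index: int
    episodes: pd.DataFrame
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    wall_values: np.ndarray | None = None
    final_value_map: np.ndarray | None = None
    summary: _metrics.ValueSummary | None = None
    total_steps: int = 0
    truncated_final: bool = False
    master_seed: int = 0


@dataclass
class ExperimentConfig:
    """Declarative description of a run batch (used by the CLI; the
    run_* functions below are the library surface)."""

    experiment: str = "painful"  # painful | relearn | disturbed
    agent: str = "ovarlap"
    maze: str = "two_goal_corridor"  # fixture id or path to an ASCII maze
    n_runs: int = 50
    n_episodes: int | None = 500
    n_total_steps: int | None = None
    theta: float = 1.0
    alpha: float = 0.1
    alpha2: float | None = None
    gamma: float = 0.95
    gamma_p: float = 0.5
    tau: float = DEFAULT_TAU
    noise_strength: float = 0.0
    noise_fraction: float = 0.0
    snapshots: tuple[int, ...] = DEFAULT_SNAPSHOTS
    randomize_start: bool = False
    switch_episode: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.n_episodes is None) == (self.n_total_steps is None):
            raise ValueError("set exactly one of n_episodes / n_total_steps")
        if self.n_episodes is not None and self.snapshots:
            bad = [e for e in self.snapshots if e > self.n_episodes]
            if bad:
                raise ValueError(f"snapshot episodes {bad} exceed run length")


def resolve_maze(maze: str | GridWorld) -> GridWorld:
    if isinstance(maze, GridWorld):
        return maze
    if maze in FIXTURES:
        return FIXTURES[maze]()
    from pathlib import Path

    from .gridworld import load_maze

    return load_maze(Path(maze).read_text())


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


def _episodic_run(world: GridWorld, kind: str, run_index: int, master_seed: int,
                  n_episodes: int, *, theta: float, tau: float, alpha: float,
                  alpha2: float | None, gamma: float, gamma_p: float,
                  snapshot_episodes: Sequence[int], randomize_start: bool,
                  switch_episode: int | None, record_wall_values: bool,
                  step_cap: int = EPISODE_STEP_CAP) -> RunResult:
    ss = _run_seed_sequence(master_seed, kind, run_index)
    policy_ss, basis_ss, tie_ss, start_ss = ss.spawn(4)
    policy_rng = np.random.default_rng(policy_ss)
    start_rng = np.random.default_rng(start_ss)
    basis_seed = int(basis_ss.generate_state(1)[0] % (2**31))
    agent = make_agent(kind, world, basis_seed=basis_seed, theta=theta,
                       alpha=alpha, alpha2=alpha2, gamma=gamma, gamma_p=gamma_p,
                       tie_rng=np.random.default_rng(tie_ss))

    active = world
    snapshots: dict[int, np.ndarray] = {}
    wall_values: list[float] = []
    rows = []
    starts = world.passable_nongoal_squares() if randomize_start else None
    for ep in range(1, n_episodes + 1):
        if switch_episode is not None and ep == switch_episode + 1:
            active = world.with_wall_penalty(0.0)
        start = None
        if starts is not None:
            start = starts[int(start_rng.integers(len(starts)))]
        trace = run_episode(active, agent, policy_rng, tau, step_cap, start,
                            record_transitions=False)
        rows.append((ep, trace.steps, trace.total_reward, trace.wall_hits,
                     trace.total_reward / trace.steps))
        if record_wall_values:
            wall_values.append(_metrics.wall_value_mean(agent.value_map(world), world))
        if ep in snapshot_episodes:
            snapshots[ep] = agent.value_map(world)
    episodes = pd.DataFrame(
        rows, columns=["episode", "steps", "total_reward", "wall_hits",
                       "reward_per_step"])
    return RunResult(
        agent_kind=kind, run_index=run_index, episodes=episodes,
        snapshots=snapshots,
        wall_values=np.asarray(wall_values) if record_wall_values else None,
        final_value_map=agent.value_map(world),
        total_steps=int(episodes["steps"].sum()), master_seed=master_seed)


def run_painful_experiment(
    world: GridWorld | str = "two_goal_corridor",
    agent_kinds: Sequence[str] = AGENT_KINDS,
    *, n_runs: int = 50, n_episodes: int = 500, theta: float = 1.0,
    alpha: float = 0.1, gamma: float = 0.95, gamma_p: float = 0.5,
    tau: float = DEFAULT_TAU, seed: int = 0,
    snapshot_episodes: Sequence[int] = DEFAULT_SNAPSHOTS,
    randomize_start: bool = False,
) -> dict[str, list[RunResult]]:
    """Painful navigation: independent runs of 500 learning episodes per
    agent kind on a painful maze, with value-map snapshots."""
    world = resolve_maze(world)
    out: dict[str, list[RunResult]] = {}
    for kind in agent_kinds:
        out[kind] = [
            _episodic_run(world, kind, run, seed, n_episodes, theta=theta,
                          tau=tau, alpha=alpha, alpha2=None, gamma=gamma,
                          gamma_p=gamma_p, snapshot_episodes=tuple(snapshot_episodes),
                          randomize_start=randomize_start, switch_episode=None,
                          record_wall_values=False)
            for run in range(n_runs)
        ]
    return out


def run_relearning_experiment(
    world: GridWorld | str = "two_goal_corridor",
    agent_kinds: Sequence[str] = AGENT_KINDS,
    *, n_runs: int = 50, switch_episode: int = 500, post_episodes: int = 500,
    theta: float = 1.0, alpha: float = 0.1, gamma: float = 0.95,
    gamma_p: float = 0.5, tau: float = DEFAULT_TAU, seed: int = 0,
) -> dict[str, list[RunResult]]:
    """Relearning after pain removal: train with painful walls up to
    ``switch_episode``, then continue with pain-free walls; the mean wall
    value is logged after every episode."""
    world = resolve_maze(world)
    n_episodes = switch_episode + post_episodes
    out: dict[str, list[RunResult]] = {}
    for kind in agent_kinds:
        out[kind] = [
            _episodic_run(world, kind, run, seed, n_episodes, theta=theta,
                          tau=tau, alpha=alpha, alpha2=None, gamma=gamma,
                          gamma_p=gamma_p, snapshot_episodes=(),
                          randomize_start=False, switch_episode=switch_episode,
                          record_wall_values=True)
            for run in range(n_runs)
        ]
    return out


def run_disturbed_experiment(
    world: GridWorld | str = "four_goal_arena",
    *, n_runs: int = 50, total_steps: int = 40_000, theta: float = 1.0,
    alpha1: float = 0.1, alpha2: float = 0.1, gamma: float = 0.8,
    tau: float = DEFAULT_TAU, noise_strength: float = 0.0,
    noise_fraction: float = 0.0, seed: int = 0,
) -> list[RunResult]:
    """Disturbed valuation on a painless arena: each run is a fixed global
    budget of environment steps (the last episode is truncated mid-flight),
    the connection noise is redrawn per run, and the final value map and
    its argmax are summarized."""
    world = resolve_maze(world)
    results = []
    for run in range(n_runs):
        ss = _run_seed_sequence(seed, "ovarlap", run)
        policy_ss, basis_ss, _, _ = ss.spawn(4)
        policy_rng = np.random.default_rng(policy_ss)
        basis_seed = int(basis_ss.generate_state(1)[0] % (2**31))
        agent = make_agent("ovarlap", world, basis_seed=basis_seed, theta=theta,
                           alpha=alpha1, alpha2=alpha2, gamma=gamma,
                           noise_strength=noise_strength,
                           noise_fraction=noise_fraction)
        rows = []
        remaining = total_steps
        ep = 0
        truncated_final = False
        while remaining > 0:
            ep += 1
            trace = run_episode(world, agent, policy_rng, tau, step_cap=remaining,
                                record_transitions=False)
            remaining -= trace.steps
            truncated_final = trace.truncated
            rows.append((ep, trace.steps, trace.total_reward, trace.wall_hits,
                         trace.total_reward / trace.steps))
        episodes = pd.DataFrame(
            rows, columns=["episode", "steps", "total_reward", "wall_hits",
                           "reward_per_step"])
        vmap = agent.value_map(world)
        results.append(RunResult(
            agent_kind="ovarlap", run_index=run, episodes=episodes,
            final_value_map=vmap, summary=_metrics.value_argmax(vmap, world),
            total_steps=total_steps, truncated_final=truncated_final,
            master_seed=seed))
    return results


def run_experiment(config: ExperimentConfig):
    """Dispatch a declarative config to the matching protocol."""
    config.validate()
    if config.experiment == "painful":
        return run_painful_experiment(
            config.maze, (config.agent,) if config.agent != "all" else AGENT_KINDS,
            n_runs=config.n_runs, n_episodes=config.n_episodes or 500,
            theta=config.theta, alpha=config.alpha, gamma=config.gamma,
            gamma_p=config.gamma_p, tau=config.tau, seed=config.seed,
            snapshot_episodes=config.snapshots,
            randomize_start=config.randomize_start)
    if config.experiment == "relearn":
        return run_relearning_experiment(
            config.maze, (config.agent,) if config.agent != "all" else AGENT_KINDS,
            n_runs=config.n_runs, switch_episode=config.switch_episode or 500,
            post_episodes=(config.n_episodes or 1000) - (config.switch_episode or 500),
            theta=config.theta, alpha=config.alpha, gamma=config.gamma,
            gamma_p=config.gamma_p, tau=config.tau, seed=config.seed)
    if config.experiment == "disturbed":
        return run_disturbed_experiment(
            config.maze if config.maze != "two_goal_corridor" else "four_goal_arena",
            n_runs=config.n_runs, total_steps=config.n_total_steps or 40_000,
            theta=config.theta, alpha1=config.alpha,
            alpha2=config.alpha if config.alpha2 is None else config.alpha2,
            gamma=config.gamma, tau=config.tau,
            noise_strength=config.noise_strength,
            noise_fraction=config.noise_fraction, seed=config.seed)
    raise ValueError(f"unknown experiment {config.experiment!r}")
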