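"""Episodic grid-world navigation environments.

The arena is a ``width x height`` grid of squares addressed by 1-based
coordinates ``(x, y)``.  An impassable border ring encloses the arena so
that every intended move target has a representable position (the value
network's input encoding only covers the grid itself).  The agent has
exactly four actions (east, west, south, north).  Moving into a passable
non-goal square succeeds with reward 0; moving into a goal delivers that
goal's positive reward and ends the episode; moving into an impassable
square is ineffective ("wall hit"): the agent stays put and receives the
world's ``wall_penalty`` (-1 in painful tasks, 0 in painless ones).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
import numpy as np

#: Fixed action order: east, west, south, north.  Displacements (dx, dy).
ACTIONS: tuple[tuple[int, int], ...] = ((1, 0), (-1, 0), (0, -1), (0, 1))
ACTION_NAMES: tuple[str, ...] = ("E", "W", "S", "N")
N_ACTIONS = 4


class MazeFormatError(ValueError):
    """Raised when ASCII maze text does not conform to the format."""


class MazeGenerationError(RuntimeError):
    """Raised when the random maze generator exhausts its retry budget."""


@dataclass(frozen=True)
class Transition:
    """One environment step.

    ``intended_target`` is the square the action pointed at, even when
    impassable; value learning always updates that square (afterstate
    convention), whereas ``next_state`` is where the agent actually is.
    """

    state: tuple[int, int]
    action: int
    reward: float
    next_state: tuple[int, int]
    terminal: bool
    wall_hit: bool
    intended_target: tuple[int, int]


class GridWorld:
    """A bounded grid maze with absorbing rewarded goals.

    Parameters
    ----------
    passable : array-like of bool, shape (width, height)
        ``passable[x-1, y-1]`` is True when square ``(x, y)`` can be
        entered.  The border ring must be impassable.
    start : (int, int)
        Starting square, 1-based.  Must be passable and not a goal.
    goals : mapping {(x, y): reward}
        Absorbing goal squares with strictly positive rewards.
    wall_penalty : float
        Reward delivered on an ineffective action; must be <= 0.
    """

    def __init__(self, passable, start, goals, wall_penalty=0.0, *, validate=True):
        self.passable = np.array(passable, dtype=bool)
        if self.passable.ndim != 2:
            raise ValueError("passable mask must be 2-D")
        self.width, self.height = self.passable.shape
        self.start = (int(start[0]), int(start[1]))
        self.goals = {(int(x), int(y)): float(r) for (x, y), r in dict(goals).items()}
        self.wall_penalty = float(wall_penalty)
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        p = self.passable
        if p[0, :].any() or p[-1, :].any() or p[:, 0].any() or p[:, -1].any():
            raise ValueError("border squares must be impassable")
        if not self.is_passable(*self.start):
            raise ValueError(f"start {self.start} is impassable")
        if self.start in self.goals:
            raise ValueError("start must not be a goal")
        if not self.goals:
            raise ValueError("at least one goal is required")
        for g, r in self.goals.items():
            if not self.is_passable(*g):
                raise ValueError(f"goal {g} is impassable")
            if r <= 0:
                raise ValueError(f"goal {g} must have positive reward, got {r}")
        if self.wall_penalty > 0:
            raise ValueError("wall_penalty must be <= 0")
        reached = self._flood_fill()
        for g in self.goals:
            if g not in reached:
                raise ValueError(f"goal {g} is unreachable from start {self.start}")

    def _flood_fill(self) -> set[tuple[int, int]]:
        """Squares reachable from start; goals are absorbing endpoints."""
        seen = {self.start}
        frontier = deque([self.start])
        while frontier:
            x, y = frontier.popleft()
            for dx, dy in ACTIONS:
                nxt = (x + dx, y + dy)
                if nxt in seen or not self.is_passable(*nxt):
                    continue
                seen.add(nxt)
                if nxt not in self.goals:  # do not walk through a goal
                    frontier.append(nxt)
        return seen

    def is_passable(self, x: int, y: int) -> bool:
        if 1 <= x <= self.width and 1 <= y <= self.height:
            return bool(self.passable[x - 1, y - 1])
        return False

    def passable_nongoal_squares(self) -> list[tuple[int, int]]:
        xs, ys = np.nonzero(self.passable)
        return [
            (int(x) + 1, int(y) + 1)
            for x, y in zip(xs, ys)
            if (int(x) + 1, int(y) + 1) not in self.goals
        ]

    def with_wall_penalty(self, wall_penalty: float) -> "GridWorld":
        """A copy of this world with a different wall penalty (validated)."""
        return GridWorld(self.passable, self.start, self.goals, wall_penalty)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridWorld):
            return NotImplemented
        return (
            np.array_equal(self.passable, other.passable)
            and self.start == other.start
            and self.goals == other.goals
            and self.wall_penalty == other.wall_penalty
        )

    # -- dynamics ----------------------------------------------------------

    def candidate_targets(self, state: tuple[int, int]) -> list[tuple[int, int]]:
        """The four intended targets in fixed action order (E, W, S, N).

        Targets may be impassable — they are valued, not entered.
        """
        x, y = state
        return [(x + dx, y + dy) for dx, dy in ACTIONS]

    def step(self, state: tuple[int, int], action: int) -> Transition:
        """Execute ``action`` from ``state``; pure in (world, state, action)."""
        x, y = state
        if not self.is_passable(x, y):
            raise ValueError(f"state {state} is impassable")
        if state in self.goals:
            raise ValueError(f"state {state} is an absorbing goal")
        dx, dy = ACTIONS[action]
        target = (x + dx, y + dy)
        if not self.is_passable(*target):
            return Transition(state, action, self.wall_penalty, state, False, True, target)
        reward = self.goals.get(target)
        if reward is not None:
            return Transition(state, action, reward, target, True, False, target)
        return Transition(state, action, 0.0, target, False, False, target)


# ---------------------------------------------------------------------------
# ASCII maze format
# ---------------------------------------------------------------------------

_GOAL_GLYPHS = ("G", "H")


def save_maze(world: GridWorld) -> str:
    """Serialize a world to ASCII: map rows (top row = max y), then
    ``key=value`` metadata lines assigning goal rewards and the wall penalty.
    """
    rewards = sorted(set(world.goals.values()))
    if len(rewards) > len(_GOAL_GLYPHS):
        raise ValueError("ASCII format supports at most two distinct goal rewards")
    glyph_of = {r: _GOAL_GLYPHS[i] for i, r in enumerate(rewards)}
    lines = []
    for y in range(world.height, 0, -1):
        row = []
        for x in range(1, world.width + 1):
            pos = (x, y)
            if pos == world.start:
                row.append("S")
            elif pos in world.goals:
                row.append(glyph_of[world.goals[pos]])
            elif world.passable[x - 1, y - 1]:
                row.append(".")
            else:
                row.append("#")
        lines.append("".join(row))
    for r, glyph in sorted(glyph_of.items(), key=lambda kv: kv[1]):
        lines.append(f"{glyph}={r:g}")
    lines.append(f"wall_penalty={world.wall_penalty:g}")
    return "\n".join(lines) + "\n"


def load_maze(text: str) -> GridWorld:
    """Parse the ASCII maze format; raises :class:`MazeFormatError` naming
    the offending line/column on malformed input."""
    raw = text.splitlines()
    map_lines: list[str] = []
    meta: dict[str, str] = {}
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if "=" in stripped and not map_lines:
            raise MazeFormatError(f"line {lineno}: metadata before map rows")
        if "=" in stripped:
            key, _, value = stripped.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif meta:
            raise MazeFormatError(f"line {lineno}: map row after metadata")
        else:
            map_lines.append((lineno, line.rstrip("\n")))  # type: ignore[arg-type]

    if not map_lines:
        raise MazeFormatError("no map rows found")
    height = len(map_lines)
    width = len(map_lines[0][1])
    rewards = {"G": 1.0, "H": 2.0}
    for glyph in _GOAL_GLYPHS:
        if glyph in meta:
            try:
                rewards[glyph] = float(meta[glyph])
            except ValueError as exc:
                raise MazeFormatError(f"bad reward for {glyph!r}: {meta[glyph]!r}") from exc
    try:
        wall_penalty = float(meta.get("wall_penalty", "0"))
    except ValueError as exc:
        raise MazeFormatError(f"bad wall_penalty: {meta['wall_penalty']!r}") from exc

    passable = np.zeros((width, height), dtype=bool)
    start = None
    goals: dict[tuple[int, int], float] = {}
    for row_idx, (lineno, row) in enumerate(map_lines):
        if len(row) != width:
            raise MazeFormatError(
                f"line {lineno}: expected {width} columns, got {len(row)}"
            )
        y = height - row_idx
        for col, ch in enumerate(row):
            x = col + 1
            if ch == "#":
                continue
            passable[x - 1, y - 1] = True
            if ch == ".":
                continue
            if ch == "S":
                if start is not None:
                    raise MazeFormatError(f"line {lineno}, column {col + 1}: duplicate 'S'")
                start = (x, y)
            elif ch in _GOAL_GLYPHS:
                goals[(x, y)] = rewards[ch]
            else:
                raise MazeFormatError(
                    f"line {lineno}, column {col + 1}: unknown glyph {ch!r}"
                )
    if start is None:
        raise MazeFormatError("map has no start square 'S'")
    if not goals:
        raise MazeFormatError("map has no goal squares")
    try:
        return GridWorld(passable, start, goals, wall_penalty)
    except ValueError as exc:
        raise MazeFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Fixture mazes
# ---------------------------------------------------------------------------


def two_goal_corridor(wall_penalty: float = -1.0) -> GridWorld:
    """Painful-task fixture: a 3-wide corridor with the start and a safe
    reward-1 goal at its ends, and a risky reward-2 goal at the end of a
    1-wide passage branching off the corridor.
    """
    passable = np.zeros((20, 20), dtype=bool)
    passable[1:19, 8:11] = True      # wide passage: x 2..19, y 9..11
    passable[11, 11:17] = True       # narrow branch: x = 12, y 12..17
    goals = {(19, 10): 1.0, (12, 17): 2.0}
    return GridWorld(passable, (2, 10), goals, wall_penalty)


def four_goal_arena(wall_penalty: float = 0.0) -> GridWorld:
    """Painless-task fixture: an open 18x18 arena with four unit-reward
    goals and a central start."""
    passable = np.zeros((20, 20), dtype=bool)
    passable[1:19, 1:19] = True
    goals = {(4, 4): 1.0, (16, 4): 1.0, (4, 16): 1.0, (16, 16): 1.0}
    return GridWorld(passable, (10, 10), goals, wall_penalty)


FIXTURES = {
    "two_goal_corridor": two_goal_corridor,
    "four_goal_arena": four_goal_arena,
}


# ---------------------------------------------------------------------------
# Rule-based random painful mazes
# ---------------------------------------------------------------------------


def _canonical_signature(world: GridWorld) -> bytes:
    """Signature invariant under the 8 square symmetries, for duplicate
    rejection in batch generation."""
    code = np.where(world.passable, 1, 0).astype(np.int32)
    sx, sy = world.start
    code[sx - 1, sy - 1] = 2
    for (gx, gy), r in world.goals.items():
        code[gx - 1, gy - 1] = 10 + int(round(2 * r))
    variants = []
    for k in range(4):
        rot = np.rot90(code, k)
        variants.append(rot.tobytes())
        variants.append(np.fliplr(rot).tobytes())
    return min(variants)


def generate_painful_maze(
    rng: np.random.Generator,
    *,
    wide_width: int = 3,
    narrow_width: int = 1,
    min_length: int = 8,
    min_branch_length: int = 4,
    size: int = 20,
    wall_penalty: float = -1.0,
    max_tries: int = 500,
) -> GridWorld:
    """Draw a random painful maze: a wide passage with the start and the
    reward-1 goal at opposite ends, and a narrow branch ending in the
    reward-2 goal."""
    lo, hi = 2, size - 1  # interior band inside the border ring
    interior = hi - lo + 1
    if wide_width < 1 or narrow_width < 1:
        raise ValueError("passage widths must be >= 1")
    if min_length > interior or wide_width + narrow_width + min_branch_length - 1 > interior:
        raise ValueError("passage dimensions do not fit the interior")

    for _ in range(max_tries):
        horizontal = bool(rng.integers(2))
        length = int(rng.integers(min_length, interior + 1))
        u0 = int(rng.integers(lo, hi - length + 2))
        u1 = u0 + length - 1
        v0 = int(rng.integers(lo, hi - wide_width + 2))
        vc = v0 + wide_width // 2

        # branch point along the passage, away from the two ends
        if u1 - 1 < u0 + 1 + narrow_width - 1:
            continue
        ub = int(rng.integers(u0 + 1, u1 - narrow_width + 1))

        sides = []
        if v0 + wide_width - 1 + min_branch_length <= hi:
            sides.append(+1)
        if v0 - min_branch_length >= lo:
            sides.append(-1)
        if not sides:
            continue
        side = sides[int(rng.integers(len(sides)))]
        if side > 0:
            room = hi - (v0 + wide_width - 1)
        else:
            room = v0 - lo
        branch_len = int(rng.integers(min_branch_length, room + 1))

        passable = np.zeros((size, size), dtype=bool)

        def carve(u_range, v_range):
            for u in u_range:
                for v in v_range:
                    x, y = (u, v) if horizontal else (v, u)
                    passable[x - 1, y - 1] = True

        carve(range(u0, u1 + 1), range(v0, v0 + wide_width))
        if side > 0:
            branch_vs = range(v0 + wide_width, v0 + wide_width + branch_len)
            v_goal = v0 + wide_width + branch_len - 1
        else:
            branch_vs = range(v0 - branch_len, v0)
            v_goal = v0 - branch_len
        carve(range(ub, ub + narrow_width), branch_vs)

        u_goal2 = ub + (narrow_width - 1) // 2
        ends = [u0, u1]
        start_u = ends[int(rng.integers(2))]
        goal1_u = u1 if start_u == u0 else u0

        def pos(u, v):
            return (u, v) if horizontal else (v, u)

        start = pos(start_u, vc)
        goals = {pos(goal1_u, vc): 1.0, pos(u_goal2, v_goal): 2.0}
        if start in goals or len(goals) != 2:
            continue
        try:
            return GridWorld(passable, start, goals, wall_penalty)
        except ValueError:
            continue
    raise MazeGenerationError(f"no valid maze after {max_tries} tries")


def generate_painful_mazes(
    rng: np.random.Generator, n: int, *, max_tries_per_maze: int = 500, **params
) -> list[GridWorld]:
    """A batch of ``n`` painful mazes, rejecting symmetric duplicates."""
    out: list[GridWorld] = []
    seen: set[bytes] = set()
    for _ in range(n):
        for _ in range(max_tries_per_maze):
            world = generate_painful_maze(rng, **params)
            sig = _canonical_signature(world)
            if sig not in seen:
                seen.add(sig)
                out.append(world)
                break
        else:
            raise MazeGenerationError(
                f"could not draw {n} distinct mazes in {max_tries_per_maze} tries each"
            )
    return out
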