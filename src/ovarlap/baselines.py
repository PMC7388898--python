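"""Comparison learners: tabular SARSA and a MaxPain variant.

Both keep look-up tables over grid squares and use the same afterstate
convention as the basis-network learner: Q(s, a) is the table value of
the square the action points to, and updates land on that square.  Neither
generalizes — a single update changes exactly one cell per table.
"""

from __future__ import annotations

import numpy as np

from .agents import td_error
from .gridworld import ACTIONS, GridWorld, Transition


class TabularAgent:
    """Plain on-policy SARSA with a single state-value table."""

    kind = "tabular"

    def __init__(self, alpha: float = 0.1, gamma: float = 0.95,
                 shape: tuple[int, int] = (20, 20)):
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        self.alpha = alpha
        self.gamma = gamma
        self.shape = shape
        self.reset()

    def reset(self) -> None:
        self.values = np.zeros(self.shape)

    def state_value(self, x: int, y: int) -> float:
        return float(self.values[x - 1, y - 1])

    def action_value(self, world: GridWorld, state, action: int) -> float:
        dx, dy = ACTIONS[action]
        return self.state_value(state[0] + dx, state[1] + dy)

    def action_values(self, world: GridWorld, state) -> np.ndarray:
        x, y = state
        v = self.values
        return np.array([v[x, y - 1], v[x - 2, y - 1], v[x - 1, y - 2], v[x - 1, y]])

    def value_map(self, world: GridWorld | None = None) -> np.ndarray:
        return self.values.copy()

    def apply_update(self, x: int, y: int, delta: float) -> None:
        """Single-cell increment by alpha * delta."""
        self.values[x - 1, y - 1] += self.alpha * delta

    def update(self, world: GridWorld, state, action: int,
               transition: Transition, next_action: int | None) -> float:
        xt, yt = transition.intended_target
        q_cur = self.state_value(xt, yt)
        if transition.terminal or next_action is None:
            q_next = 0.0
        else:
            q_next = self.action_value(world, transition.next_state, next_action)
        delta = td_error(transition.reward, self.gamma, q_next, q_cur,
                         transition.terminal)
        self.apply_update(xt, yt, delta)
        return delta

    def state_dict(self) -> dict:
        return {"kind": self.kind, "alpha": self.alpha, "gamma": self.gamma,
                "values": self.values.tolist()}

    def load_state_dict(self, state: dict) -> None:
        self.values = np.asarray(state["values"], dtype=float).copy()


def maxpain_split(reward: float) -> tuple[float, float]:
    """Rectified split of a signed reward into (reward, pain) components:
    (max(r, 0), max(-r, 0))."""
    return max(reward, 0.0), max(-reward, 0.0)


class MaxPainAgent:
    """Dual-table learner with separate reward and pain values.

    The reward table learns on-policy (SARSA) from the rectified positive
    reward; the pain table learns off-policy from the rectified negative
    reward, bootstrapping on the action that minimizes the combined value
    Q_L(s', .) — i.e. it predicts the worst case.  Decisions and the
    exported value map use the unnormalized combination v_L = v_r - v_p.
    """

    kind = "maxpain"

    def __init__(self, alpha_r: float = 0.1, alpha_p: float = 0.1,
                 gamma_r: float = 0.95, gamma_p: float = 0.5,
                 shape: tuple[int, int] = (20, 20),
                 rng: np.random.Generator | None = None):
        for a in (alpha_r, alpha_p):
            if a < 0:
                raise ValueError("learning rates must be >= 0")
        for g in (gamma_r, gamma_p):
            if not 0.0 <= g < 1.0:
                raise ValueError("discount factors must lie in [0, 1)")
        self.alpha_r = alpha_r
        self.alpha_p = alpha_p
        self.gamma_r = gamma_r
        self.gamma_p = gamma_p
        self.shape = shape
        # own stream for argmin tie-breaking (ties are ubiquitous early on)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.reset()

    def reset(self) -> None:
        self.v_r = np.zeros(self.shape)
        self.v_p = np.zeros(self.shape)

    # -- valuation ---------------------------------------------------------

    def state_value(self, x: int, y: int) -> float:
        return float(self.v_r[x - 1, y - 1] - self.v_p[x - 1, y - 1])

    def action_value(self, world: GridWorld, state, action: int) -> float:
        dx, dy = ACTIONS[action]
        return self.state_value(state[0] + dx, state[1] + dy)

    def action_values(self, world: GridWorld, state) -> np.ndarray:
        x, y = state
        vl = self.v_r - self.v_p
        return np.array([vl[x, y - 1], vl[x - 2, y - 1], vl[x - 1, y - 2], vl[x - 1, y]])

    def value_map(self, world: GridWorld | None = None) -> np.ndarray:
        return self.v_r - self.v_p

    # -- learning ----------------------------------------------------------

    def _worst_case_action(self, world: GridWorld, state) -> int:
        """argmin over Q_L(state, .); ties broken uniformly at random."""
        q_l = self.action_values(world, state)
        minimum = q_l.min()
        candidates = np.flatnonzero(q_l == minimum)
        if len(candidates) == 1:
            return int(candidates[0])
        return int(candidates[self.rng.integers(len(candidates))])

    def errors(self, world: GridWorld, state, action: int,
               transition: Transition, next_action: int | None) -> tuple[float, float]:
        """(δ_r, δ_p) for the executed step; terminal steps zero both
        bootstrap terms."""
        r_plus, r_minus = maxpain_split(transition.reward)
        xt, yt = transition.intended_target
        qr_cur = float(self.v_r[xt - 1, yt - 1])
        qp_cur = float(self.v_p[xt - 1, yt - 1])
        if transition.terminal or next_action is None:
            boot_r = 0.0
            boot_p = 0.0
        else:
            nxt = transition.next_state
            dx, dy = ACTIONS[next_action]
            boot_r = self.gamma_r * float(self.v_r[nxt[0] + dx - 1, nxt[1] + dy - 1])
            worst = self._worst_case_action(world, nxt)
            wx, wy = ACTIONS[worst]
            boot_p = self.gamma_p * float(self.v_p[nxt[0] + wx - 1, nxt[1] + wy - 1])
        return r_plus + boot_r - qr_cur, r_minus + boot_p - qp_cur

    def apply_update(self, x: int, y: int, delta_r: float, delta_p: float) -> None:
        self.v_r[x - 1, y - 1] += self.alpha_r * delta_r
        self.v_p[x - 1, y - 1] += self.alpha_p * delta_p

    def update(self, world: GridWorld, state, action: int,
               transition: Transition, next_action: int | None) -> tuple[float, float]:
        delta_r, delta_p = self.errors(world, state, action, transition, next_action)
        xt, yt = transition.intended_target
        self.apply_update(xt, yt, delta_r, delta_p)
        return delta_r, delta_p

    def state_dict(self) -> dict:
        return {"kind": self.kind, "alpha_r": self.alpha_r, "alpha_p": self.alpha_p,
                "gamma_r": self.gamma_r, "gamma_p": self.gamma_p,
                "v_r": self.v_r.tolist(), "v_p": self.v_p.tolist()}

    def load_state_dict(self, state: dict) -> None:
        self.v_r = np.asarray(state["v_r"], dtype=float).copy()
        self.v_p = np.asarray(state["v_p"], dtype=float).copy()
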