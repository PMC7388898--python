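"""The dual-channel value learner ("OVaRLAP").

Two readout weight vectors over the fixed basis play the roles of striatal
D1- and D2-pathway populations: ``w1`` feeds the positive pre-output
channel d1 and grows on positive TD errors, ``w2`` feeds the negative
channel d2 and grows on negative TD errors.  The state value is
v = d1 - d2; action values follow the afterstate convention
Q(s, a) = v(x', y') at the square the action points to.  The learning
rule is SARSA with a normalized update Δw = α δ h / Σ h² applied at the
afterstate, which guarantees that the value of the updated square moves
by exactly α1·δ (δ > 0) or α2·δ (δ < 0) — shared basis responses then
spread that increment to nearby squares (generalization), and the
opposing channel later trims over-spread value (discrimination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisNetwork
from .gridworld import ACTIONS, GridWorld, Transition


def td_error(reward: float, gamma: float, q_next: float, q_cur: float,
             terminal: bool = False) -> float:
    """SARSA TD error δ = r + γ·Q(s', a') - Q(s, a); terminal steps drop
    the bootstrap term."""
    bootstrap = 0.0 if terminal else gamma * q_next
    return reward + bootstrap - q_cur


@dataclass(frozen=True)
class OVaRLAPParams:
    """Learning metaparameters.  ``alpha2 = 0`` disables learning from
    negative TD errors (the "impaired" disturbance)."""

    alpha1: float = 0.1
    alpha2: float = 0.1
    gamma: float = 0.95

    def validate(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("learning rates must be >= 0")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")


class OVaRLAPAgent:
    """Dual-channel SARSA learner over a fixed basis network."""

    kind = "ovarlap"

    def __init__(self, basis: BasisNetwork, params: OVaRLAPParams | None = None):
        self.basis = basis
        self.params = params or OVaRLAPParams()
        self.params.validate()
        self.reset()

    def reset(self) -> None:
        """Zero both channels so every state starts at value zero."""
        n = self.basis.spec.n_hidden
        self.w1 = np.zeros(n)
        self.w2 = np.zeros(n)
        self._wdiff = np.zeros(n)  # w1 - w2, maintained incrementally

    # -- valuation ---------------------------------------------------------

    def channel_values(self, x: int, y: int) -> tuple[float, float]:
        h = self.basis.hidden_activity(x, y)
        return float(self.w1 @ h), float(self.w2 @ h)

    def state_value(self, x: int, y: int) -> float:
        return float(self._wdiff @ self.basis.hidden_activity(x, y))

    def action_value(self, world: GridWorld, state, action: int) -> float:
        dx, dy = ACTIONS[action]
        return self.state_value(state[0] + dx, state[1] + dy)

    def action_values(self, world: GridWorld, state) -> np.ndarray:
        """Afterstate values of the four intended targets, in action order."""
        x, y = state
        rows = self.basis.M[(x, x - 2, x - 1, x - 1), (y - 1, y - 1, y - 2, y)]
        return rows @ self._wdiff

    def value_map(self, world: GridWorld | None = None) -> np.ndarray:
        """v(x, y) on every square, as a (width, height) grid."""
        spec = self.basis.spec
        return (self.basis.M_flat @ self._wdiff).reshape(spec.width, spec.height)

    # -- learning ----------------------------------------------------------

    def apply_update(self, x: int, y: int, delta: float) -> None:
        """Asymmetric normalized update at afterstate (x, y).

        δ > 0 grows w1, δ < 0 grows w2, δ = 0 is a no-op; either way the
        post-update value at (x, y) differs from the pre-update value by
        exactly alpha1·δ or alpha2·δ.
        """
        if delta == 0.0:
            return
        h = self.basis.hidden_activity(x, y)
        norm = float(h @ h)
        if norm <= 0.0:
            raise ArithmeticError(f"zero hidden activity norm at ({x}, {y})")
        if delta > 0.0:
            step = (self.params.alpha1 * delta / norm) * h
            self.w1 += step
            self._wdiff += step
        else:
            step = (self.params.alpha2 * (-delta) / norm) * h
            self.w2 += step
            self._wdiff -= step

    def update(self, world: GridWorld, state, action: int,
               transition: Transition, next_action: int | None) -> float:
        """One SARSA update for the executed (s, a); returns δ.

        ``next_action`` is the on-policy action already drawn at the actual
        next state (None on terminal steps, which zero the bootstrap).
        """
        xt, yt = transition.intended_target
        q_cur = self.state_value(xt, yt)
        if transition.terminal or next_action is None:
            q_next = 0.0
        else:
            nx, ny = transition.next_state
            dx, dy = ACTIONS[next_action]
            q_next = self.state_value(nx + dx, ny + dy)
        delta = td_error(transition.reward, self.params.gamma, q_next, q_cur,
                         transition.terminal)
        self.apply_update(xt, yt, delta)
        return delta

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": {
                "alpha1": self.params.alpha1,
                "alpha2": self.params.alpha2,
                "gamma": self.params.gamma,
            },
            "basis_seed": self.basis.spec.seed,
            "w1": self.w1.tolist(),
            "w2": self.w2.tolist(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.w1 = np.asarray(state["w1"], dtype=float).copy()
        self.w2 = np.asarray(state["w2"], dtype=float).copy()
        self._wdiff = self.w1 - self.w2
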