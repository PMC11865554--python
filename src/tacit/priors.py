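"""Movement priors, state priors, their combination, and Shannon surprise.

The Sender's expectations about "ordinary" motion come from two sources:

* a *movement prior* rooted in naive kinetics — a moving token is expected to
  keep going straight, turns are less likely, reversals least likely:
  p(f) > p(l) = p(r) > p(b);
* a *state prior* encoding goal orientation — an inverse-power field that
  equals 1 at the Sender's goal and decays with grid distance,
  p(s) = alpha^(-d).

Both are combined multiplicatively over the feasible moves of the current
state and renormalized (a normalization, not a softmax).  The Shannon
surprise of a move, h(a|s) = -log2 p(a|s), is the model's signalling
currency: the Sender marks the Receiver's goal by choosing improbable moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .gridworld import Board, State, neighbors, relative_direction

__all__ = [
    "LAMBDA_BOUNDS", "GAMMA_BOUNDS",
    "MovementParams", "MovementPriorVector", "StateParams",
    "movement_prior", "state_prior", "combined_action_prior", "surprise",
]

LAMBDA_BOUNDS = (0.001, 0.3)
GAMMA_BOUNDS = (2.0, 10.0)


@dataclass(frozen=True)
class MovementParams:
    """Kinetic-prior parameters: lam = p(backward), gamma = p(f)/(p(l)+p(r)).

    Bounds follow the fitted boxes (lam in [0.001, 0.3], gamma in [2, 10]).
    ``strict=False`` relaxes them for demonstrations such as the lam = 0,
    gamma = 2 worked example.
    """

    lam: float
    gamma: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict:
            if not (LAMBDA_BOUNDS[0] <= self.lam <= LAMBDA_BOUNDS[1]):
                raise ValueError(f"lambda {self.lam} outside {LAMBDA_BOUNDS}")
            if not (GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]):
                raise ValueError(f"gamma {self.gamma} outside {GAMMA_BOUNDS}")
        else:
            if not (0.0 <= self.lam < 1.0) or self.gamma <= 0:
                raise ValueError("lambda must be in [0,1), gamma positive")


class MovementPriorVector(NamedTuple):
    """Prior over egocentric moves; sums to 1."""

    p_f: float
    p_l: float
    p_r: float
    p_b: float

    def by_relative(self, rel: str) -> float:
        return {"F": self.p_f, "L": self.p_l, "R": self.p_r, "B": self.p_b}[rel]


def movement_prior(params: MovementParams) -> MovementPriorVector:
    """Expand (lam, gamma) into the four egocentric move probabilities.

    p(b) = lam; p(f) = gamma/(gamma+1) * (1-lam);
    p(l) = p(r) = 0.5 * (1 - gamma/(gamma+1)) * (1-lam).
    With gamma = 2 and lam = 0 this gives p(f) = 2/3 and p(l) = p(r) = 1/6.
    """
    lam, gamma = params.lam, params.gamma
    p_b = lam
    p_f = gamma / (gamma + 1.0) * (1.0 - lam)
    p_lr = 0.5 * (1.0 - gamma / (gamma + 1.0)) * (1.0 - lam)
    return MovementPriorVector(p_f, p_lr, p_lr, p_b)


@dataclass(frozen=True)
class StateParams:
    """Slope of the goal-orientation field; alpha > 1 so the field decays."""

    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha > 1.0:
            raise ValueError("alpha must be > 1 for a decreasing state prior")


def state_prior(board: Board, sender_goal: State, params: StateParams) -> np.ndarray:
    """Inverse-power field alpha^(-d) over the board, peaking (=1) at the goal.

    Distance is the Manhattan metric of the 4-connected grid, so equal-prior
    contours are diamonds rather than circles.
    """
    if not board.on_board(sender_goal):
        raise ValueError("sender_goal must be on the board")
    rows = np.abs(np.arange(board.n_rows) - sender_goal[0])[:, None]
    cols = np.abs(np.arange(board.n_cols) - sender_goal[1])[None, :]
    return params.alpha ** (-(rows + cols).astype(float))


def combined_action_prior(mv: MovementPriorVector, heading: Optional[int],
                          field: np.ndarray, s: State,
                          board: Board = None) -> dict[int, float]:
    """Per-move probabilities from movement x state priors at state ``s``.

    Each feasible absolute move m gets weight p(m relative to heading) x
    field[target of m]; weights are renormalized over the feasible moves only
    (infeasible moves off the board carry no mass and are never scored).
    Before the first move there is no heading and the movement factor is
    uniform, so the distribution is driven by the state prior alone.
    """
    if board is None:
        board = Board(*field.shape)
    weights: dict[int, float] = {}
    for d, target in neighbors(board, s):
        if heading is None:
            w_m = 1.0
        else:
            w_m = mv.by_relative(relative_direction(heading, d))
        weights[d] = w_m * float(field[target])
    total = sum(weights.values())
    if total <= 0.0:
        raise ValueError("combined prior has zero total mass")
    return {d: w / total for d, w in weights.items()}


def surprise(dist: dict[int, float], a: int) -> float:
    """Shannon surprise -log2 p(a|s) of taking move ``a`` (bits)."""
    if a not in dist:
        raise ValueError(f"move {a} is not in the support of the distribution")
    return -math.log2(dist[a])
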