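"""Board geometry, headings, trajectories and rewards for the Tacit Communication Game.

The TCG is played on a small rectangular grid (4x4 in the original task).  A
Sender moves a token from a shared start location to her own goal, and the
trajectory itself is the message that must convey the Receiver's goal.  This
module holds the purely geometric layer: 4-connected moves, egocentric
(relative) move directions, trial typing and the points-remaining reward.

Conventions
-----------
* States are 0-based ``(row, col)`` tuples, row-major.
* Absolute directions are integer codes ``N, E, S, W`` (0..3, clockwise).
* A *heading* is the absolute direction of the last move, or ``None`` before
  the first move (the first move of a message has no predefined direction).
* Relative directions: ``F`` (same as heading), ``B`` (opposite), ``L``
  (counter-clockwise of heading, viewed from above with north up) and ``R``
  (clockwise); the first move is coded ``"first"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "N", "E", "S", "W", "DIRECTION_NAMES", "DIRECTION_VECTORS",
    "Board", "BOARD_4X4", "GoalConfiguration", "Message",
    "neighbors", "relative_direction", "shortest_path_length",
    "classify_trial", "remaining_reward", "heading_of", "apply_move",
]

State = tuple[int, int]

N, E, S, W = 0, 1, 2, 3
DIRECTION_NAMES = ("N", "E", "S", "W")
DIRECTION_VECTORS = ((-1, 0), (0, 1), (1, 0), (0, -1))


@dataclass(frozen=True)
class Board:
    """Rectangular 4-connected grid (no obstacles, no diagonal moves)."""

    n_rows: int = 4
    n_cols: int = 4

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("board dimensions must be positive")

    def on_board(self, s: State) -> bool:
        r, c = s
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def states(self) -> Iterator[State]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield (r, c)

    def central_states(self) -> tuple[State, ...]:
        """The four middle cells of an even-sided board (start locations)."""
        r0, c0 = self.n_rows // 2 - 1, self.n_cols // 2 - 1
        return ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1))


BOARD_4X4 = Board(4, 4)


def apply_move(s: State, direction: int) -> State:
    dr, dc = DIRECTION_VECTORS[direction]
    return (s[0] + dr, s[1] + dc)


def neighbors(board: Board, s: State) -> list[tuple[int, State]]:
    """Feasible ``(direction, target)`` pairs from ``s`` (2-4 entries)."""
    if not board.on_board(s):
        raise ValueError(f"state {s} is off the {board.n_rows}x{board.n_cols} board")
    out = []
    for d in (N, E, S, W):
        t = apply_move(s, d)
        if board.on_board(t):
            out.append((d, t))
    return out


def relative_direction(heading: Optional[int], move: int) -> str:
    """Egocentric label of ``move`` given the previous move's direction.

    Returns ``"first"`` when there is no heading yet.  ``L`` is the
    counter-clockwise quarter-turn of the heading (e.g. heading E, move N -> L).
    """
    if heading is None:
        return "first"
    delta = (move - heading) % 4
    return ("F", "R", "B", "L")[delta]


def heading_of(prev: State, cur: State) -> int:
    """Absolute direction of the move ``prev -> cur`` (must be 4-adjacent)."""
    dr, dc = cur[0] - prev[0], cur[1] - prev[1]
    try:
        return DIRECTION_VECTORS.index((dr, dc))
    except ValueError:
        raise ValueError(f"states {prev} and {cur} are not 4-adjacent") from None


def shortest_path_length(board: Board, a: State, b: State) -> int:
    """Moves needed between two states: Manhattan distance on an open grid."""
    if not (board.on_board(a) and board.on_board(b)):
        raise ValueError("states must be on the board")
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


@dataclass(frozen=True)
class GoalConfiguration:
    """Start, Sender goal and Receiver goal of one TCG trial."""

    start: State
    sender_goal: State
    receiver_goal: State
    board: Board = field(default=BOARD_4X4)

    def __post_init__(self) -> None:
        for name in ("start", "sender_goal", "receiver_goal"):
            if not self.board.on_board(getattr(self, name)):
                raise ValueError(f"{name} {getattr(self, name)} is off the board")
        if self.sender_goal == self.start:
            raise ValueError("sender_goal must differ from start")
        if self.receiver_goal == self.start:
            raise ValueError("receiver_goal must differ from start")


def classify_trial(config: GoalConfiguration) -> str:
    """``"direct"`` if the Receiver's goal lies on some shortest start->sender-goal path.

    On an open grid this is the Manhattan-distance identity
    d(start, rg) + d(rg, sg) == d(start, sg); otherwise the Sender must leave
    the direct path to enter the Receiver's goal (``"indirect"``).
    """
    b = config.board
    via = (shortest_path_length(b, config.start, config.receiver_goal)
           + shortest_path_length(b, config.receiver_goal, config.sender_goal))
    return "direct" if via == shortest_path_length(b, config.start, config.sender_goal) else "indirect"


def remaining_reward(config: GoalConfiguration, s_next: State, steps_taken: int,
                     receiver_goal_visited: bool) -> float:
    """Points left from the initial ten after the cheapest legal completion.

    The message costs one point per step.  From ``s_next`` the cheapest
    completion runs through the Receiver's goal (if not yet visited) and on to
    the Sender's goal.  Values may go negative on long trajectories; they are
    deliberately not clamped so the urgency gradient survives.
    """
    if steps_taken < 1:
        raise ValueError("steps_taken counts the move into s_next; must be >= 1")
    b = config.board
    if receiver_goal_visited:
        remaining = shortest_path_length(b, s_next, config.sender_goal)
    else:
        remaining = (shortest_path_length(b, s_next, config.receiver_goal)
                     + shortest_path_length(b, config.receiver_goal, config.sender_goal))
    return 10.0 - steps_taken - remaining


@dataclass
class Message:
    """An ordered trajectory of states starting at the trial's start location."""

    states: list[State]
    step_surprise: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a message needs at least one move")
        for a, b in zip(self.states, self.states[1:]):
            heading_of(a, b)  # raises on non-adjacent pairs

    @property
    def n_moves(self) -> int:
        return len(self.states) - 1

    @property
    def actions(self) -> list[int]:
        """Absolute direction of every move."""
        return [heading_of(a, b) for a, b in zip(self.states, self.states[1:])]

    @property
    def relative_actions(self) -> list[str]:
        """Egocentric labels; the first entry is always ``"first"``."""
        acts = self.actions
        out, heading = [], None
        for a in acts:
            out.append(relative_direction(heading, a))
            heading = a
        return out

    def visits(self, s: State) -> bool:
        return s in self.states

    def arrival_step(self, s: State) -> Optional[int]:
        """1-based index of the move that first enters ``s`` (None if never)."""
        for i, st in enumerate(self.states[1:], start=1):
            if st == s:
                return i
        return None


def validate_message(message: Message, config: GoalConfiguration,
                     require_complete: bool = True) -> None:
    """Check a message against its goal configuration (bounds, start, endpoint)."""
    for s in message.states:
        if not config.board.on_board(s):
            raise ValueError(f"trajectory state {s} is off the board")
    if message.states[0] != config.start:
        raise ValueError("message must begin at the start location")
    if require_complete and message.states[-1] != config.sender_goal:
        raise ValueError("complete messages must end at the sender's goal")
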