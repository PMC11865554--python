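"""Plain-text trial tables.

Schema (CSV or JSON-lines; one row per trial):

==================  =====================================================
column              content
==================  =====================================================
subject_id          opaque subject label
trial_index         0-based trial counter within subject
start               ``"r,c"`` 0-based (row, col) of the start cell
sender_goal         ``"r,c"``
receiver_goal       ``"r,c"``
trajectory          ``"r,c;r,c;..."`` ordered states, first = start
receiver_choice     ``"r,c"`` or empty when unavailable
success             1 if receiver_choice == receiver_goal, else 0/empty
==================  =====================================================

The loader validates board bounds and 4-adjacency of consecutive states and
round-trips losslessly with the writer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .behavior import TrialRecord
from .gridworld import BOARD_4X4, Board, GoalConfiguration, Message

__all__ = ["save_trials", "load_trials"]


def _fmt(state) -> str:
    return f"{state[0]},{state[1]}"


def _parse_state(text: str) -> tuple[int, int]:
    r, c = text.split(",")
    return (int(r), int(c))


def _record_row(rec: TrialRecord, trial_index: int) -> dict:
    return {
        "subject_id": rec.subject_id,
        "trial_index": trial_index,
        "start": _fmt(rec.config.start),
        "sender_goal": _fmt(rec.config.sender_goal),
        "receiver_goal": _fmt(rec.config.receiver_goal),
        "trajectory": ";".join(_fmt(s) for s in rec.message.states),
        "receiver_choice": "" if rec.receiver_choice is None else _fmt(rec.receiver_choice),
        "success": ("" if rec.receiver_choice is None
                    else int(rec.receiver_choice == rec.config.receiver_goal)),
    }


def save_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    """Write records as CSV (``.csv``) or JSON-lines (anything else)."""
    path = Path(path)
    trial_counter: dict = {}
    rows = []
    for rec in records:
        idx = trial_counter.get(rec.subject_id, 0)
        trial_counter[rec.subject_id] = idx + 1
        rows.append(_record_row(rec, idx))
    if path.suffix == ".csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def load_trials(path: str | Path, board: Board = BOARD_4X4) -> list[TrialRecord]:
    """Load and validate a trial table (format chosen by extension)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, keep_default_na=False)
        rows = df.to_dict("records")
    else:
        with open(path) as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    records = []
    for row in rows:
        config = GoalConfiguration(
            start=_parse_state(str(row["start"])),
            sender_goal=_parse_state(str(row["sender_goal"])),
            receiver_goal=_parse_state(str(row["receiver_goal"])),
            board=board,
        )
        states = [_parse_state(s) for s in str(row["trajectory"]).split(";")]
        message = Message(states)  # validates adjacency
        if message.states[0] != config.start:
            raise ValueError("trajectory must begin at the start cell")
        choice_text = str(row.get("receiver_choice", "") or "")
        choice: Optional[tuple[int, int]] = (_parse_state(choice_text)
                                             if choice_text else None)
        records.append(TrialRecord(subject_id=row["subject_id"], config=config,
                                   message=message, receiver_choice=choice))
    return records
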