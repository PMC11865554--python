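"""Model-free behavioral indices: message types, profiles and accuracy.

Senders in the TCG converge on a handful of recognisable strategies.  Three
types recur: *Enter-Exit* (a single reversal, stepping into the Receiver's
goal and back out before heading home), *Wiggly* (repeated oscillation
between two adjacent cells) and *Pass-By* (a straight pass through the goal
with no reversal).  Classification here is by immediate reversals —
egocentric ``B`` moves — with an explicit residual ``other`` category so
unusual trajectories are never force-binned.  The rule table is exposed so
alternative codings can be swapped in and compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence
import warnings

import pandas as pd

from .gridworld import GoalConfiguration, Message, classify_trial

__all__ = [
    "MESSAGE_TYPES", "MessageProfile", "message_profile",
    "classify_message", "reversal_rule_classifier", "summarize_indices",
    "IndexSummary", "TrialRecord",
]

MESSAGE_TYPES = ("enter_exit", "wiggly", "pass_by", "other")


class MessageProfile(NamedTuple):
    """Counts of egocentric move directions, first move excluded."""

    n_F: int
    n_L: int
    n_R: int
    n_B: int


def message_profile(message: Message) -> MessageProfile:
    """Count relative directions of moves 2..n (the first move has none)."""
    rel = message.relative_actions[1:]
    if not rel:
        warnings.warn("single-move message has an all-zero profile", stacklevel=2)
    return MessageProfile(rel.count("F"), rel.count("L"), rel.count("R"),
                          rel.count("B"))


def _reversal_positions(message: Message) -> list[int]:
    """0-based move indices whose egocentric label is B (immediate reversal)."""
    return [i for i, r in enumerate(message.relative_actions) if r == "B"]


def reversal_rule_classifier(message: Message) -> str:
    """Default type rule, keyed on the number and shape of immediate reversals.

    0 reversals -> pass_by; exactly 1 -> enter_exit; >= 2 reversals that all
    oscillate between the same two adjacent cells -> wiggly; anything else
    -> other.
    """
    rev = _reversal_positions(message)
    if len(rev) == 0:
        return "pass_by"
    if len(rev) == 1:
        return "enter_exit"
    # wiggly: the reversal moves bounce between one pair of adjacent cells
    pairs = {frozenset((message.states[i], message.states[i + 1])) for i in rev}
    if len(pairs) == 1:
        return "wiggly"
    return "other"


def classify_message(message: Message, config: Optional[GoalConfiguration] = None,
                     rule: Callable[[Message], str] = reversal_rule_classifier,
                     ) -> str:
    """Assign one of enter_exit / wiggly / pass_by / other to a trajectory.

    The type is a function of the relative-action sequence alone; ``config``
    is only used to flag messages that never visit the Receiver's goal (they
    are classifiable but non-communicative).
    """
    label = rule(message)
    if config is not None and not message.visits(config.receiver_goal):
        warnings.warn("message never visits the receiver's goal "
                      "(classified but non-communicative)", stacklevel=2)
    return label


@dataclass
class TrialRecord:
    """One Sender trial with the Receiver's choice (None if unavailable)."""

    subject_id: object
    config: GoalConfiguration
    message: Message
    receiver_choice: Optional[tuple[int, int]] = None


@dataclass
class IndexSummary:
    """Per-subject and group behavioral indices.

    ``type_freq``: per-subject type frequencies (rows: subject, columns:
    message types), overall and per trial type; ``profiles``: mean profile
    per message type; ``accuracy``: Receiver success rate per type.  Group
    rows report mean and standard error across subjects.
    """

    type_freq: pd.DataFrame            # index (subject), columns types
    type_freq_by_trial: pd.DataFrame   # index (subject, trial_type)
    profiles: pd.DataFrame             # index (subject, type), columns F/L/R/B
    accuracy: pd.DataFrame             # index (subject, type incl. 'overall')

    def group_type_freq(self) -> pd.DataFrame:
        return _mean_se(self.type_freq)

    def group_type_freq_by_trial(self) -> pd.DataFrame:
        return self.type_freq_by_trial.groupby(level="trial_type").agg(["mean", "sem"])

    def group_profiles(self) -> pd.DataFrame:
        return self.profiles.groupby(level="type").agg(["mean", "sem"])

    def group_accuracy(self) -> pd.DataFrame:
        return self.accuracy.groupby(level="type").agg(["mean", "sem"])


def _mean_se(df: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"mean": df.mean(axis=0), "sem": df.sem(axis=0)})


def summarize_indices(records: Sequence[TrialRecord]) -> IndexSummary:
    """Compute type frequencies, profiles and accuracy from a trial dataset."""
    if not records:
        raise ValueError("empty dataset")
    rows = []
    for rec in records:
        mtype = classify_message(rec.message)
        prof = message_profile(rec.message)
        rows.append({
            "subject": rec.subject_id,
            "trial_type": classify_trial(rec.config),
            "type": mtype,
            "F": prof.n_F, "L": prof.n_L, "R": prof.n_R, "B": prof.n_B,
            "correct": (None if rec.receiver_choice is None
                        else float(rec.receiver_choice == rec.config.receiver_goal)),
        })
    df = pd.DataFrame(rows)

    def freq_table(sub: pd.DataFrame) -> pd.Series:
        return (sub["type"].value_counts(normalize=True)
                .reindex(MESSAGE_TYPES, fill_value=0.0))

    type_freq = df.groupby("subject").apply(freq_table, include_groups=False)
    by_trial = (df.groupby(["subject", "trial_type"])
                .apply(freq_table, include_groups=False))
    by_trial.index.names = ["subject", "trial_type"]
    profiles = (df.groupby(["subject", "type"])[["F", "L", "R", "B"]].mean())
    profiles.index.names = ["subject", "type"]

    if df["correct"].notna().any():
        per_type = df.dropna(subset=["correct"]).groupby(["subject", "type"])["correct"].mean()
        overall = df.dropna(subset=["correct"]).groupby("subject")["correct"].mean()
        acc = per_type.to_frame("accuracy")
        overall.index = pd.MultiIndex.from_product([overall.index, ["overall"]],
                                                   names=["subject", "type"])
        acc = pd.concat([acc, overall.to_frame("accuracy")]).sort_index()
    else:
        acc = pd.DataFrame(columns=["accuracy"],
                           index=pd.MultiIndex.from_arrays([[], []],
                                                           names=["subject", "type"]))
    return IndexSummary(type_freq=type_freq, type_freq_by_trial=by_trial,
                        profiles=profiles, accuracy=acc)
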