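"""Sessionization, qualification, outcome labeling and time-based splitting.

A *consultation* is a maximal run of messages in one chat with no
inter-message silence of six hours or more. A chatter's first consultation
with at least 3 counselor messages and at least 10 messages overall is the
*index consultation*; the binary outcome is whether any later consultation
(with at least one chatter message) begins within 188 days of the index
consultation's end.

Two APIs are provided: per-chat functions over :class:`Message` /
:class:`Consultation` objects (the contract the tests exercise against
brute-force oracles), and vectorized corpus-level functions over pandas
frames used by the analysis drivers at full scale. A consistency test ties
the two together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Message",
    "Consultation",
    "ChatterEpisodes",
    "segment_sessions",
    "qualifies",
    "build_episodes",
    "label_outcome",
    "sessionize_corpus",
    "build_records",
    "time_split",
    "outcome_window_sensitivity",
]

GAP_HOURS_DEFAULT = 6.0
WINDOW_DAYS_DEFAULT = 188
MIN_COUNSELOR_DEFAULT = 3
MIN_TOTAL_DEFAULT = 10

SENDERS = ("chatter", "counselor")


@dataclass(frozen=True)
class Message:
    chat_id: str
    sender: str
    sent_at: pd.Timestamp
    text: str

    def __post_init__(self) -> None:
        if self.sender not in SENDERS:
            raise ValueError(f"sender must be one of {SENDERS}, got {self.sender!r}")


@dataclass
class Consultation:
    """A gap-delimited run of messages within one chat."""

    chat_id: str
    messages: list[Message] = field(default_factory=list)

    @property
    def start_at(self) -> pd.Timestamp:
        return self.messages[0].sent_at

    @property
    def end_at(self) -> pd.Timestamp:
        return self.messages[-1].sent_at

    @property
    def n_chatter(self) -> int:
        return sum(m.sender == "chatter" for m in self.messages)

    @property
    def n_counselor(self) -> int:
        return sum(m.sender == "counselor" for m in self.messages)

    @property
    def n_total(self) -> int:
        return len(self.messages)

    def word_count(self, sender: str | None = None) -> int:
        msgs = self.messages if sender is None else [
            m for m in self.messages if m.sender == sender
        ]
        return sum(len(m.text.split()) for m in msgs)


@dataclass
class ChatterEpisodes:
    """All consultations of one chatter plus the index/label bookkeeping."""

    chat_id: str
    consultations: list[Consultation]
    index_consultation: Consultation | None = None
    label: bool | None = None


def segment_sessions(
    messages: Sequence[Message], gap_hours: float = GAP_HOURS_DEFAULT
) -> list[Consultation]:
    """Partition one chat's messages into consultations.

    Messages are sorted by timestamp and split greedily: a new consultation
    starts whenever the silence since the previous message is >= gap_hours
    (a gap of exactly the threshold starts a new consultation).
    """
    if not messages:
        return []
    chat_ids = {m.chat_id for m in messages}
    if len(chat_ids) > 1:
        raise ValueError(f"messages span multiple chats: {sorted(chat_ids)}")
    ordered = sorted(messages, key=lambda m: m.sent_at)
    gap = pd.Timedelta(hours=gap_hours)
    out: list[Consultation] = [Consultation(ordered[0].chat_id, [ordered[0]])]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.sent_at - prev.sent_at >= gap:
            out.append(Consultation(cur.chat_id, []))
        out[-1].messages.append(cur)
    return out


def qualifies(
    c: Consultation,
    min_counselor: int = MIN_COUNSELOR_DEFAULT,
    min_total: int = MIN_TOTAL_DEFAULT,
) -> bool:
    """Whether a consultation counts as an actual counseling session:
    at least `min_counselor` counselor messages and `min_total` messages."""
    return c.n_counselor >= min_counselor and c.n_total >= min_total


def build_episodes(
    messages: Sequence[Message],
    gap_hours: float = GAP_HOURS_DEFAULT,
    min_counselor: int = MIN_COUNSELOR_DEFAULT,
    min_total: int = MIN_TOTAL_DEFAULT,
    window_days: int = WINDOW_DAYS_DEFAULT,
) -> ChatterEpisodes:
    """Sessionize one chat, pick the index consultation, attach the label."""
    cons = segment_sessions(messages, gap_hours)
    ep = ChatterEpisodes(messages[0].chat_id if messages else "", cons)
    for c in cons:
        if qualifies(c, min_counselor, min_total):
            ep.index_consultation = c
            break
    if ep.index_consultation is not None:
        ep.label = label_outcome(ep, window_days)
    return ep


def label_outcome(e: ChatterEpisodes, window_days: int = WINDOW_DAYS_DEFAULT) -> bool:
    """True iff a later consultation with >=1 chatter message starts within
    `window_days` (inclusive) of the index consultation's end.

    Messages within six hours of the index consultation belong to the same
    consultation by construction and therefore never count as recontact.
    """
    if e.index_consultation is None:
        raise ValueError("label undefined: chatter has no index consultation")
    limit = e.index_consultation.end_at + pd.Timedelta(days=window_days)
    for c in e.consultations:
        if c.start_at > e.index_consultation.end_at and c.start_at <= limit:
            if c.n_chatter >= 1:
                return True
    return False


# ---------------------------------------------------------------------------
# vectorized corpus-level pipeline


def sessionize_corpus(
    messages: pd.DataFrame, gap_hours: float = GAP_HOURS_DEFAULT
) -> pd.DataFrame:
    """Sessionize a whole message frame at once.

    Returns one row per consultation with columns ``chat_id, session,
    start_at, end_at, n_chatter, n_counselor, n_total, words_chatter,
    words_counselor, words_total``.
    """
    df = messages.sort_values(["chat_id", "sent_at"], kind="mergesort").reset_index(
        drop=True
    )
    gap = pd.Timedelta(hours=gap_hours)
    new_chat = df["chat_id"].ne(df["chat_id"].shift())
    silence = df["sent_at"].diff() >= gap
    df["session"] = (new_chat | silence).cumsum()
    words = df["text"].fillna("").str.split().str.len()
    is_ch = df["sender"].eq("chatter")
    df["_w_ch"] = words.where(is_ch, 0)
    df["_w_co"] = words.where(~is_ch, 0)
    df["_n_ch"] = is_ch.astype(int)
    agg = df.groupby(["chat_id", "session"], sort=True).agg(
        start_at=("sent_at", "first"),
        end_at=("sent_at", "last"),
        n_total=("sent_at", "size"),
        n_chatter=("_n_ch", "sum"),
        words_chatter=("_w_ch", "sum"),
        words_counselor=("_w_co", "sum"),
    )
    agg["n_counselor"] = agg["n_total"] - agg["n_chatter"]
    agg["words_total"] = agg["words_chatter"] + agg["words_counselor"]
    agg = agg.reset_index()
    agg["session"] = agg.groupby("chat_id").cumcount()
    return agg


def build_records(
    consultations: pd.DataFrame,
    min_counselor: int = MIN_COUNSELOR_DEFAULT,
    min_total: int = MIN_TOTAL_DEFAULT,
    window_days: int = WINDOW_DAYS_DEFAULT,
) -> pd.DataFrame:
    """Pick each chatter's index consultation and label the outcome.

    Chatters with no qualifying consultation are dropped (they never
    received an actual counseling session). Returns one row per labeled
    chatter: index session identifiers, message/word counts and ``label``.
    """
    q = (consultations["n_counselor"] >= min_counselor) & (
        consultations["n_total"] >= min_total
    )
    idx = (
        consultations[q]
        .sort_values(["chat_id", "start_at"], kind="mergesort")
        .groupby("chat_id", as_index=False)
        .first()
    )
    idx = idx.rename(columns={"session": "index_session"})
    later = consultations.merge(
        idx[["chat_id", "index_session", "end_at"]].rename(
            columns={"end_at": "index_end"}
        ),
        on="chat_id",
    )
    window = pd.Timedelta(days=window_days)
    hit = (
        (later["start_at"] > later["index_end"])
        & (later["start_at"] <= later["index_end"] + window)
        & (later["n_chatter"] >= 1)
    )
    recontact = later.loc[hit, "chat_id"].unique()
    out = idx.rename(
        columns={"start_at": "index_start", "end_at": "index_end"}
    )[
        [
            "chat_id", "index_session", "index_start", "index_end",
            "n_chatter", "n_counselor", "n_total",
            "words_chatter", "words_counselor", "words_total",
        ]
    ].copy()
    out["label"] = out["chat_id"].isin(recontact)
    return out


def time_split(
    records: pd.DataFrame, cutoff: str | pd.Timestamp
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chronological split on the index consultation's start.

    Records starting strictly before ``cutoff`` form the train set; the
    cutoff itself belongs to the test set. Warns (does not fail) if either
    side is empty.
    """
    cutoff = pd.Timestamp(cutoff)
    in_train = records["index_start"] < cutoff
    train, test = records[in_train], records[~in_train]
    if len(train) == 0 or len(test) == 0:
        import warnings

        warnings.warn("time_split produced an empty side", stacklevel=2)
    return train, test


def outcome_window_sensitivity(
    consultations: pd.DataFrame,
    eval_fn: Callable[[pd.DataFrame], float],
    windows: Iterable[int] = range(150, 211, 10),
    min_counselor: int = MIN_COUNSELOR_DEFAULT,
    min_total: int = MIN_TOTAL_DEFAULT,
) -> tuple[list[float], float]:
    """Relabel the corpus at each outcome window and score each labeling.

    ``eval_fn`` maps a labeled record frame to a score (e.g. a CV AUROC).
    Returns the per-window scores and their standard deviation — small
    values indicate the prediction task is insensitive to the exact
    outcome horizon, as expected when most recontacts happen early.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one outcome window")
    scores = [
        float(
            eval_fn(
                build_records(
                    consultations,
                    min_counselor=min_counselor,
                    min_total=min_total,
                    window_days=w,
                )
            )
        )
        for w in windows
    ]
    return scores, float(np.std(scores))
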