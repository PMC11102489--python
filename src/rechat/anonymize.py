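"""Privacy-preserving text transformation.

Reproduces the four-step anonymization pipeline applied before any
analysis: (1) whole-token replacement of names and city names with
``[NAME]`` / ``[CITY]`` tokens, (2) stemming through a pluggable stemmer,
(3) shuffling of stems into random order within each speaker, destroying
narrative order, and (4) deletion of every stem present in fewer than
`min_chats` distinct chats, so no surviving stem uniquely identifies a
conversation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AnonymizationConfig",
    "SpeakerDoc",
    "tokenize",
    "replace_pii",
    "stem_tokens",
    "shuffle_within_speaker",
    "prune_rare",
    "anonymize_corpus",
    "build_speaker_docs",
]

_PUNCT = ".,;:!?\"'()[]{}«»„“”‘’-–—…/\\"


@dataclass
class AnonymizationConfig:
    name_list: tuple[str, ...] = ()
    city_list: tuple[str, ...] = ()
    name_token: str = "[NAME]"
    city_token: str = "[CITY]"
    min_chats: int = 5
    shuffle_seed: int = 0
    stemmer: Callable[[str], str] = field(default=lambda tok: tok)

    def __post_init__(self) -> None:
        if self.min_chats < 1:
            raise ValueError("min_chats must be >= 1")


@dataclass
class SpeakerDoc:
    """One channel (chatter or counselor) of one chat as a stem multiset.

    After shuffling, stem order carries no information; the list form just
    preserves multiplicities.
    """

    chat_id: str
    channel: str
    stems: list[str]


def tokenize(text: str, cfg: AnonymizationConfig | None = None) -> list[str]:
    """Lowercase, split on whitespace, strip flanking punctuation.

    Digits are kept as tokens (numbers such as a stated age are
    predictive). The PII placeholder tokens pass through unchanged.
    """
    keep = {cfg.name_token, cfg.city_token} if cfg else set()
    out = []
    for raw in text.split():
        if raw in keep:
            out.append(raw)
            continue
        tok = raw.lower().strip(_PUNCT)
        if tok:
            out.append(tok)
    return out


def _pii_pattern(entries: Iterable[str]) -> re.Pattern | None:
    entries = [e for e in entries if e]
    if not entries:
        return None
    alts = "|".join(re.escape(e) for e in sorted(entries, key=len, reverse=True))
    return re.compile(rf"(?<!\w)(?:{alts})(?!\w)", re.IGNORECASE)


def replace_pii(text: str, cfg: AnonymizationConfig) -> str:
    """Replace every whole-token, case-insensitive occurrence of a listed
    name/city with its placeholder token; all other text is untouched."""
    pat_name = _pii_pattern(cfg.name_list)
    pat_city = _pii_pattern(cfg.city_list)
    if pat_name is not None:
        text = pat_name.sub(cfg.name_token, text)
    if pat_city is not None:
        text = pat_city.sub(cfg.city_token, text)
    return text


def stem_tokens(tokens: Iterable[str], cfg: AnonymizationConfig) -> list[str]:
    """Map each token through the configured stemmer; placeholder tokens
    pass through unchanged."""
    keep = {cfg.name_token, cfg.city_token}
    return [tok if tok in keep else cfg.stemmer(tok) for tok in tokens]


def shuffle_within_speaker(doc: SpeakerDoc, seed: int) -> SpeakerDoc:
    """Seeded uniform permutation of one speaker's stems (multiset kept)."""
    rng = np.random.default_rng(seed)
    stems = list(doc.stems)
    rng.shuffle(stems)
    return SpeakerDoc(doc.chat_id, doc.channel, stems)


def prune_rare(docs: list[SpeakerDoc], min_chats: int = 5) -> list[SpeakerDoc]:
    """Delete every stem present in fewer than `min_chats` distinct chats.

    Presence is counted at chat level: a stem used by both speakers of one
    chat counts once. Stems in exactly `min_chats` chats are retained.
    """
    chats_per_stem: dict[str, set[str]] = {}
    for d in docs:
        for s in set(d.stems):
            chats_per_stem.setdefault(s, set()).add(d.chat_id)
    keep = {s for s, chats in chats_per_stem.items() if len(chats) >= min_chats}
    return [
        SpeakerDoc(d.chat_id, d.channel, [s for s in d.stems if s in keep])
        for d in docs
    ]


def anonymize_corpus(
    raw_docs: list[tuple[str, str, str]], cfg: AnonymizationConfig
) -> list[SpeakerDoc]:
    """Full anonymization of (chat_id, channel, text) triples:
    PII replacement -> tokenization -> stemming -> within-speaker shuffle
    -> rare-stem deletion across the whole corpus."""
    docs = []
    for i, (chat_id, channel, text) in enumerate(raw_docs):
        toks = stem_tokens(tokenize(replace_pii(text, cfg), cfg), cfg)
        doc = shuffle_within_speaker(
            SpeakerDoc(chat_id, channel, toks), cfg.shuffle_seed + i
        )
        docs.append(doc)
    return prune_rare(docs, cfg.min_chats)


def build_speaker_docs(
    messages: pd.DataFrame,
    records: pd.DataFrame,
    cfg: AnonymizationConfig | None = None,
) -> pd.DataFrame:
    """Anonymized per-speaker documents of each index consultation.

    Restricts the message stream to each labeled chatter's index
    consultation, runs the anonymization pipeline per channel, and returns
    one row per chat with space-joined ``chatter_doc`` / ``counselor_doc``
    columns (empty string when a channel is silent).
    """
    cfg = cfg or AnonymizationConfig()
    win = records[["chat_id", "index_start", "index_end"]]
    m = messages.merge(win, on="chat_id", how="inner")
    m = m[(m["sent_at"] >= m["index_start"]) & (m["sent_at"] <= m["index_end"])]
    joined = (
        m.groupby(["chat_id", "sender"])["text"]
        .apply(lambda s: " ".join(s))
        .unstack(fill_value="")
        .reindex(columns=["chatter", "counselor"], fill_value="")
    )
    raw = []
    for chat_id, row in joined.iterrows():
        raw.append((chat_id, "chatter", row["chatter"]))
        raw.append((chat_id, "counselor", row["counselor"]))
    docs = anonymize_corpus(raw, cfg)
    frame: dict[str, dict[str, str]] = {}
    for d in docs:
        frame.setdefault(d.chat_id, {})[d.channel] = " ".join(d.stems)
    out = pd.DataFrame(
        {
            "chat_id": list(frame),
            "chatter_doc": [frame[c].get("chatter", "") for c in frame],
            "counselor_doc": [frame[c].get("counselor", "") for c in frame],
        }
    )
    return records.merge(out, on="chat_id", how="left").fillna(
        {"chatter_doc": "", "counselor_doc": ""}
    )
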