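import numpy as np
import pandas as pd
import pytest

from rechat import anonymize, features, sessions, synth


@pytest.fixture(scope="session")
def small_corpus():
    """A small default-configured corpus shared across tests."""
    cfg = synth.SynthConfig(n_chatters=400, seed=11)
    messages, truth = synth.generate_corpus(cfg)
    return cfg, messages, truth


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    """Labeled records + anonymized speaker docs + baseline features."""
    _, messages, _ = small_corpus
    cons = sessions.sessionize_corpus(messages)
    records = sessions.build_records(cons)
    docs = anonymize.build_speaker_docs(messages, records)
    return features.make_dataset(docs)


def make_messages(chat_id, hours, senders=None, texts=None, base="2022-01-01"):
    """Build a toy message list at the given clock offsets (in hours)."""
    t0 = pd.Timestamp(base)
    n = len(hours)
    senders = senders or ["chatter"] * n
    texts = texts or ["hallo"] * n
    return [
        sessions.Message(chat_id, s, t0 + pd.Timedelta(hours=h), x)
        for h, s, x in zip(hours, senders, texts)
    ]


@pytest.fixture
def toy_messages():
    return make_messages
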