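"""Feature construction: dual-channel TF-IDF and the metadata baseline.

Each chatter's index consultation yields two documents — the chatter's
stems and the counselor's stems. Each channel gets its own TF-IDF
vectorizer (raw term counts, optional smoothed IDF, Euclidean
normalization per channel vector) with channel-specific document-frequency
bounds: ``min_df`` is an absolute chat count, ``max_df`` a proportion of
chats. The two channel vectors are concatenated; columns carry ``CH:`` /
``CO:`` prefixes. The metadata baseline uses only the two channel word
counts and the clock hour of the first message.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

__all__ = [
    "VectorizerParams",
    "DualVectorizer",
    "make_dataset",
    "baseline_matrix",
    "BASELINE_COLUMNS",
]

BASELINE_COLUMNS = ["words_chatter", "words_counselor", "hour"]


@dataclass(frozen=True)
class VectorizerParams:
    """Document-frequency bounds and IDF switch, per channel.

    Defaults are the best configuration found by the hyperparameter search
    at full scale: a term must appear in at least `min_df_*` chats
    (absolute) and at most `max_df_*` (proportion) of chats of its channel.
    """

    max_df_chatter: float = 0.8
    min_df_chatter: int = 150
    max_df_couns: float = 0.3
    min_df_couns: int = 75
    use_idf: bool = False

    def __post_init__(self) -> None:
        for v in (self.max_df_chatter, self.max_df_couns):
            if not 0.0 < v <= 1.0:
                raise ValueError("max_df must be a proportion in (0, 1]")
        for v in (self.min_df_chatter, self.min_df_couns):
            if v < 1:
                raise ValueError("min_df is an absolute chat count >= 1")


def _channel_vectorizer(min_df: int, max_df: float, use_idf: bool) -> TfidfVectorizer:
    # docs are pre-tokenized space-joined stems; splitting is the analyzer
    return TfidfVectorizer(
        analyzer=str.split,
        lowercase=False,
        min_df=int(min_df),
        max_df=float(max_df),
        use_idf=use_idf,
        smooth_idf=True,
        sublinear_tf=False,
        norm="l2",
    )


class DualVectorizer:
    """Two per-channel TF-IDF vectorizers whose outputs are concatenated.

    Fitted only on training documents; the vocabulary is frozen before any
    held-out chat is transformed.
    """

    def __init__(self, params: VectorizerParams | None = None) -> None:
        self.params = params or VectorizerParams()
        self._chatter: TfidfVectorizer | None = None
        self._couns: TfidfVectorizer | None = None

    def fit(self, chatter_docs, counselor_docs) -> "DualVectorizer":
        p = self.params
        self._chatter = _channel_vectorizer(p.min_df_chatter, p.max_df_chatter, p.use_idf)
        self._couns = _channel_vectorizer(p.min_df_couns, p.max_df_couns, p.use_idf)
        try:
            self._chatter.fit(chatter_docs)
            self._couns.fit(counselor_docs)
        except ValueError as err:
            raise ValueError(f"empty vocabulary under {p}: {err}") from err
        return self

    def transform(self, chatter_docs, counselor_docs) -> sp.csr_matrix:
        if self._chatter is None or self._couns is None:
            raise RuntimeError("vectorizer not fitted")
        return sp.hstack(
            [self._chatter.transform(chatter_docs), self._couns.transform(counselor_docs)],
            format="csr",
        )

    def fit_transform(self, chatter_docs, counselor_docs) -> sp.csr_matrix:
        return self.fit(chatter_docs, counselor_docs).transform(
            chatter_docs, counselor_docs
        )

    @property
    def feature_names(self) -> list[str]:
        return [f"CH:{w}" for w in self._chatter.get_feature_names_out()] + [
            f"CO:{w}" for w in self._couns.get_feature_names_out()
        ]

    @property
    def n_features(self) -> tuple[int, int]:
        """(chatter vocabulary size, counselor vocabulary size)."""
        return (
            len(self._chatter.get_feature_names_out()),
            len(self._couns.get_feature_names_out()),
        )

    # --- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        state = {"params": asdict(self.params), "channels": {}}
        for name, vec in (("chatter", self._chatter), ("counselor", self._couns)):
            vocab = {w: int(i) for w, i in vec.vocabulary_.items()}
            idf = vec.idf_.tolist() if self.params.use_idf else None
            state["channels"][name] = {"vocabulary": vocab, "idf": idf}
        Path(path).write_text(json.dumps(state))

    @classmethod
    def from_json(cls, path: str | Path) -> "DualVectorizer":
        state = json.loads(Path(path).read_text())
        self = cls(VectorizerParams(**state["params"]))
        self._chatter = _channel_vectorizer(
            self.params.min_df_chatter, self.params.max_df_chatter, self.params.use_idf
        )
        self._couns = _channel_vectorizer(
            self.params.min_df_couns, self.params.max_df_couns, self.params.use_idf
        )
        from sklearn.feature_extraction.text import TfidfTransformer

        for name, vec in (("chatter", self._chatter), ("counselor", self._couns)):
            ch = state["channels"][name]
            vec.vocabulary_ = ch["vocabulary"]
            vec.fixed_vocabulary_ = True
            vec._tfidf = TfidfTransformer(
                norm="l2", use_idf=self.params.use_idf,
                smooth_idf=True, sublinear_tf=False,
            )
            # mark as fitted; real idf weights are restored below
            vec._tfidf.fit(sp.csr_matrix((1, len(ch["vocabulary"]))))
            if self.params.use_idf:
                vec._tfidf.idf_ = np.asarray(ch["idf"])
        return self


def make_dataset(docs: pd.DataFrame) -> pd.DataFrame:
    """Attach the baseline features to a labeled speaker-doc frame.

    Expects the output of :func:`rechat.anonymize.build_speaker_docs`
    (records merged with ``chatter_doc`` / ``counselor_doc``); adds the
    clock ``hour`` of the index consultation start.
    """
    out = docs.copy()
    out["hour"] = pd.to_datetime(out["index_start"]).dt.hour
    return out


def baseline_matrix(dataset: pd.DataFrame) -> np.ndarray:
    """Metadata baseline design matrix: chatter word count, counselor word
    count, hour of day (0-23) of the index consultation start."""
    return dataset[BASELINE_COLUMNS].to_numpy(dtype=float)
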