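"""Explainability: TreeSHAP attributions, stem co-occurrence context and
embedding-based clustering of stems.

Attributions come from XGBoost's exact tree-path SHAP implementation
(``pred_contribs``), which satisfies local accuracy: per sample, the base
value plus the per-feature attributions reproduces the model's margin
output. Because single stems are hard to read in isolation (word order
was destroyed by the anonymization), two context layers are added: a
cross-channel co-occurrence table for any target stem, and a k-means
clustering of stem embedding vectors with the number of clusters chosen
by the silhouette score, each cluster summarized by the summed
mean-absolute attribution of its members.

The embedding provider is pluggable: word2vec-format text vectors can be
loaded from a file, or count-based embeddings (positive PMI + truncated
SVD over document co-occurrence) can be trained on the corpus itself so
that no external download is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from xgboost import DMatrix

from .modeling import TextPipeline

__all__ = [
    "ShapReport",
    "CooccurrenceTable",
    "ClusterReport",
    "shap_attribution",
    "cooccurrence",
    "embed_cluster",
    "load_word2vec_text",
    "PpmiSvdEmbeddings",
]


@dataclass
class ShapReport:
    """Per-sample, per-feature additive attributions of the text model."""

    base_value: float
    attributions: np.ndarray  # (n_samples, n_features)
    feature_names: list[str]
    margins: np.ndarray  # model margin output per sample

    @property
    def mean_abs(self) -> pd.Series:
        return pd.Series(
            np.abs(self.attributions).mean(axis=0), index=self.feature_names
        ).sort_values(ascending=False)

    @property
    def n_features_per_channel(self) -> dict[str, int]:
        return {
            "chatter": sum(f.startswith("CH:") for f in self.feature_names),
            "counselor": sum(f.startswith("CO:") for f in self.feature_names),
        }

    def additivity_gap(self) -> float:
        """Max |base + sum(attributions) - margin| over samples."""
        recon = self.base_value + self.attributions.sum(axis=1)
        return float(np.abs(recon - self.margins).max())

    def top_features(self, k: int = 20) -> pd.Series:
        return self.mean_abs.head(k)

    def to_frame(self) -> pd.DataFrame:
        ma = self.mean_abs
        return pd.DataFrame(
            {
                "feature": ma.index,
                "channel": [f.split(":", 1)[0] for f in ma.index],
                "stem": [f.split(":", 1)[1] for f in ma.index],
                "mean_abs_shap": ma.to_numpy(),
            }
        )


def shap_attribution(pipeline: TextPipeline, dataset: pd.DataFrame) -> ShapReport:
    """Exact TreeSHAP attribution for every sample and feature.

    Delegates to the booster's native tree explainer; the returned report
    satisfies base + sum(attributions) = margin per sample.
    """
    X = pipeline.design_matrix(dataset)
    booster = pipeline.model.get_booster()
    dm = DMatrix(X)
    contribs = booster.predict(dm, pred_contribs=True)
    margins = booster.predict(dm, output_margin=True)
    return ShapReport(
        base_value=float(contribs[0, -1]),
        attributions=np.asarray(contribs[:, :-1]),
        feature_names=pipeline.feature_names,
        margins=np.asarray(margins),
    )


@dataclass
class CooccurrenceTable:
    """Cross-channel context of one target stem.

    ``counts`` gives, for each other-channel stem, the number of chats
    containing both it and the target; ``share`` the fraction of
    target-chats covered. ``cross_channel_share`` is the fraction of
    target-chats whose *other* channel also contains the target stem
    itself (the mirroring share).
    """

    target: str
    target_channel: str
    n_target_chats: int
    counts: pd.Series
    cross_channel_share: float

    @property
    def share(self) -> pd.Series:
        return self.counts / max(self.n_target_chats, 1)


def cooccurrence(
    dataset: pd.DataFrame, target: str, target_channel: str, top_k: int = 20
) -> CooccurrenceTable:
    """Most frequent other-channel stems among chats using a target stem.

    ``dataset`` carries the anonymized ``chatter_doc`` / ``counselor_doc``
    columns. Returns an empty table when the target never occurs.
    """
    if target_channel not in ("chatter", "counselor"):
        raise ValueError("target_channel must be 'chatter' or 'counselor'")
    tgt_col = f"{target_channel}_doc"
    oth_col = "counselor_doc" if target_channel == "chatter" else "chatter_doc"
    tgt_sets = dataset[tgt_col].str.split().map(set)
    has_target = tgt_sets.map(lambda s: target in s)
    n_target = int(has_target.sum())
    if n_target == 0:
        return CooccurrenceTable(target, target_channel, 0, pd.Series(dtype=int), 0.0)
    other_sets = dataset.loc[has_target, oth_col].str.split().map(set)
    counter: dict[str, int] = {}
    mirrored = 0
    for s in other_sets:
        if target in s:
            mirrored += 1
        for stem in s:
            counter[stem] = counter.get(stem, 0) + 1
    counts = pd.Series(counter).sort_values(ascending=False).head(top_k).astype(int)
    return CooccurrenceTable(
        target, target_channel, n_target, counts, mirrored / n_target
    )


# ---------------------------------------------------------------------------
# embedding providers


def load_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Parse word2vec text format (optional count/dim header line)."""
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 2 or not first[0].isdigit():
            # no header: the first line is already a vector
            vectors[first[0]] = np.array(first[1:], dtype=float)
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    return vectors


class PpmiSvdEmbeddings:
    """Count-based stem embeddings trained on the corpus itself.

    Document-level co-occurrence counts are reweighted by positive
    pointwise mutual information and factorized by truncated SVD; stems
    that occur in similar chats land near each other. A train-on-corpus
    provider keeps the clustering stage self-contained (no external
    vector file), at the cost of coarser semantics than large pretrained
    embeddings.
    """

    def __init__(self, dim: int = 50, seed: int = 0) -> None:
        self.dim = dim
        self.seed = seed
        self.vectors: dict[str, np.ndarray] = {}

    def fit(self, documents: list[list[str]]) -> "PpmiSvdEmbeddings":
        vocab = sorted({w for doc in documents for w in doc})
        index = {w: i for i, w in enumerate(vocab)}
        rows, cols = [], []
        for j, doc in enumerate(documents):
            for w in set(doc):
                rows.append(index[w])
                cols.append(j)
        X = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(vocab), len(documents))
        )
        co = (X @ X.T).toarray()  # stem-by-stem shared-document counts
        total = co.sum()
        row = co.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log((co * total) / (row * row.T))
        ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
        k = min(self.dim, len(vocab) - 1)
        u, s, _ = svds(
            sp.csr_matrix(ppmi), k=k, random_state=np.random.default_rng(self.seed)
        )
        order = np.argsort(s)[::-1]
        emb = u[:, order] * np.sqrt(s[order])
        self.vectors = {w: emb[i] for w, i in index.items()}
        return self

    def __getitem__(self, stem: str) -> np.ndarray:
        return self.vectors[stem]

    def __contains__(self, stem: str) -> bool:
        return stem in self.vectors


@dataclass
class ClusterReport:
    """k-means grouping of stems with silhouette-chosen k."""

    assignments: pd.Series  # stem -> cluster id
    k: int
    silhouette_by_k: pd.Series
    cluster_importance: pd.Series  # summed mean-|attribution| per cluster
    cluster_sizes: pd.Series
    n_embedded: int
    n_missing: int


def embed_cluster(
    stems: list[str],
    importances: pd.Series,
    provider,
    k_range: range | list[int] = range(5, 41),
    seed: int = 0,
    min_k: int | None = None,
    cosine: bool = False,
) -> ClusterReport:
    """Cluster stems in embedding space and sum attributions per cluster.

    Stems missing from the provider's vocabulary are excluded and counted.
    For each candidate k a seeded k-means with multiple restarts is fitted;
    k maximizes the mean silhouette, optionally subject to a usability
    floor ``min_k`` (few large clusters are rarely readable even when they
    score well).
    """
    embedded = [s for s in stems if s in provider]
    n_missing = len(stems) - len(embedded)
    ks = [k for k in k_range if k < len(embedded)]
    if min_k is not None:
        ks = [k for k in ks if k >= min_k]
    if not ks:
        raise ValueError(
            f"only {len(embedded)} embeddable stems; no candidate k is feasible"
        )
    X = np.vstack([np.asarray(provider[s], dtype=float) for s in embedded])
    if cosine:
        X = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    sil = {}
    labels_by_k = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(X)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(X, lab)) if len(set(lab)) > 1 else -1.0
    sil = pd.Series(sil)
    best_k = int(sil.idxmax())
    lab = labels_by_k[best_k]
    assign = pd.Series(lab, index=embedded, name="cluster")
    imp = importances.groupby(level=0).sum().reindex(embedded).fillna(0.0)
    cluster_importance = imp.groupby(assign).sum().sort_values(ascending=False)
    sizes = assign.value_counts().sort_index()
    return ClusterReport(
        assignments=assign,
        k=best_k,
        silhouette_by_k=sil,
        cluster_importance=cluster_importance,
        cluster_sizes=sizes,
        n_embedded=len(embedded),
        n_missing=n_missing,
    )
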