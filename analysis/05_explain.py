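#!/usr/bin/env python
"""Explain the fitted model: SHAP attributions, co-occurrence, clusters.

Ranks word-stem features by mean |SHAP| on the train set, pulls the
cross-channel co-occurrence context of the top self-harm stem, and
groups all predictor stems by k-means over corpus-trained PPMI-SVD
embeddings, with the number of clusters chosen by the silhouette curve
(subject to a usability floor). An external word2vec text file can be
substituted via --embeddings.
"""

import argparse
from pathlib import Path

import pandas as pd

from rechat import explain, modeling

ROOT = Path(__file__).resolve().parents[1]
import importlib.util

_spec = importlib.util.spec_from_file_location(
    "tune_train", Path(__file__).parent / "03_tune_train.py"
)
_tt = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_tt)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--embeddings", default=None,
                    help="word2vec text file; default trains PPMI-SVD on corpus")
    ap.add_argument("--k-min", type=int, default=5)
    ap.add_argument("--k-max", type=int, default=20)
    args = ap.parse_args()

    train, y = _tt.load_dataset("train")
    pipe = modeling.TextPipeline.load(ROOT / "scratch" / "model")
    rep = explain.shap_attribution(pipe, train)
    n = rep.n_features_per_channel
    print(f"{n['chatter']} chatter and {n['counselor']} counselor stems "
          f"included as predictors (additivity gap {rep.additivity_gap():.2e})")
    rep.to_frame().to_csv(ROOT / "results" / "shap_features.csv", index=False)
    print("top 10 stems by mean |SHAP|:")
    print(rep.top_features(10).round(4).to_string())

    top_harm = next(
        (f for f in rep.mean_abs.index if f.split(":")[1] in
         ("verletz", "ritz", "schneid", "narb", "wund")), None)
    if top_harm:
        ch = "chatter" if top_harm.startswith("CH:") else "counselor"
        stem = top_harm.split(":")[1]
        table = explain.cooccurrence(train, stem, ch, top_k=15)
        table.counts.rename("n_chats").to_csv(
            ROOT / "results" / f"cooccurrence_{stem}.csv"
        )
        print(f"\n'{stem}' ({ch}): used in {table.n_target_chats} chats; "
              f"mirrored by the other channel in "
              f"{table.cross_channel_share:.2f} of them")

    if args.embeddings:
        provider = explain.load_word2vec_text(args.embeddings)
    else:
        docs = [
            (c + " " + o).split()
            for c, o in zip(train.chatter_doc, train.counselor_doc)
        ]
        provider = explain.PpmiSvdEmbeddings(dim=50, seed=0).fit(docs)

    stems = sorted({f.split(":")[1] for f in rep.mean_abs.index})
    importances = rep.mean_abs.rename(index=lambda f: f.split(":")[1])
    clus = explain.embed_cluster(
        stems, importances, provider,
        k_range=range(args.k_min, args.k_max + 1), seed=0, min_k=args.k_min,
    )
    print(f"\nclustered {clus.n_embedded} stems ({clus.n_missing} without a "
          f"vector) into k={clus.k} clusters")
    print("cluster summed |SHAP| (top 5):")
    print(clus.cluster_importance.head(5).round(4).to_string())
    pd.DataFrame(
        {"stem": clus.assignments.index, "cluster": clus.assignments.values}
    ).to_csv(ROOT / "results" / "stem_clusters.csv", index=False)
    clus.silhouette_by_k.rename("silhouette").to_csv(
        ROOT / "results" / "silhouette_curve.csv"
    )


if __name__ == "__main__":
    main()
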