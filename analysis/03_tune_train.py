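#!/usr/bin/env python
"""Tune and fit the text pipeline on the train split.

Anonymizes the index consultations into per-speaker stem bags, then
jointly tunes the dual-channel TF-IDF document-frequency bounds and the
booster hyperparameters by Bayesian search (SMBO over the discrete
grids), scoring each configuration by repeated stratified CV AUROC.
The search here is a scaled-down run (see docs/methods.md for the
problem sizes); pass --n-iter 250 --n-repeats 5 for a full-scale search.
Writes the search trace and the final fitted model bundle.
"""

import argparse
from pathlib import Path

import yaml

from rechat import anonymize, features, io, modeling

ROOT = Path(__file__).resolve().parents[1]


def load_dataset(split: str):
    messages = io.read_messages_jsonl(ROOT / "scratch" / "corpus.jsonl")
    records = io.read_table(
        ROOT / "results" / "records.csv", date_cols=("index_start", "index_end")
    )
    records = records[records.split == split].reset_index(drop=True)
    docs = anonymize.build_speaker_docs(messages, records)
    ds = features.make_dataset(docs)
    return ds, ds.label.astype(str).str.lower().eq("true").to_numpy()


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-iter", type=int, default=10)
    ap.add_argument("--n-folds", type=int, default=3)
    ap.add_argument("--n-repeats", type=int, default=1)
    ap.add_argument("--n-rounds", type=int, default=150)
    ap.add_argument("--seed", type=int, default=5)
    args = ap.parse_args()

    train, y = load_dataset("train")
    print(f"train set: {len(train)} chatters, prevalence {y.mean():.3f}")

    best, trace = modeling.bayes_search(
        train, y, n_iter=args.n_iter, seed=args.seed,
        n_folds=args.n_folds, n_repeats=args.n_repeats, n_rounds=args.n_rounds,
    )
    trace.to_csv(ROOT / "results" / "search_trace.csv", index=False)
    print(f"searched {len(trace)} configurations; "
          f"best CV AUROC {trace.score.max():.4f}")
    print("best configuration:")
    print(yaml.safe_dump({"vec": best.vec.__dict__,
                          "booster": best.booster.__dict__}))

    pipe = modeling.fit_final(train, y, best, seed=args.seed)
    pipe.save(ROOT / "scratch" / "model")
    n_ch, n_co = pipe.vectorizer.n_features
    print(f"final model: {n_ch} chatter + {n_co} counselor stem features")


if __name__ == "__main__":
    main()
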