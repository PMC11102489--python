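# rechat

Predicting **recurrent contact** at a 24/7 chat-counseling service for
young people, from the text of the first consultation alone.

Chat hotlines are a first access point into mental healthcare; knowing
which help seekers will come back lets a service step up care or redirect
early. `rechat` implements the full prediction pipeline for this task as
it can be run on heavily anonymized routine data — conversations reduced
to per-speaker word-stem bags in randomized order — together with a
synthetic corpus generator that emulates the statistical structure of
such a service's data, so every stage is testable without any real chat
logs.

## The task and the model

Each chatter's messages are sessionized with a six-hour silence rule; a
consultation with ≥3 counselor messages and ≥10 messages overall counts
as an actual counseling session, and the first such *index consultation*
anchors the outcome: did the chatter start a new consultation within 188
days of its end?

Features are two channel-separated TF-IDF vectors over the anonymized
stem bags — one for the chatter's words, one for the counselor's — with
channel-specific document-frequency bounds (min_df absolute, max_df
proportional), concatenated and fed to an XGBoost classifier with a
logistic objective. A word-count + hour-of-day booster serves as the
metadata baseline. All eleven hyperparameters (4 df bounds, the IDF
switch, 6 booster parameters) are tuned **jointly** by Bayesian search
over discrete grids, maximizing repeated stratified 5-fold CV AUROC.
Evaluation is a one-time prediction on a chronological holdout, with a
label-permutation test against chance and a corrected 5×2cv paired
t-test against the baseline. Explainability stacks TreeSHAP attributions,
cross-channel stem co-occurrence, and k-means clustering of stem
embeddings with a silhouette-chosen number of clusters.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic corpus (outputs land in `results/`, the large regenerable
corpus in `scratch/`):

```bash
python analysis/01_simulate.py --n 4000 --seed 7
python analysis/02_sessionize_label.py
python analysis/03_tune_train.py
python analysis/04_evaluate.py
python analysis/05_explain.py
```

A run at these settings prints, among other things:

```
4000 labeled chatters (2923 train / 1077 test at 2022-09-01)
  n_chatter          25.7    20.7
  n_counselor        17.9    11.9
  words_total       455.9   280.3
recontact prevalence 0.422
...
holdout n=1077: AUROC 0.648 (permutation p = 0.0010)
metadata baseline holdout AUROC 0.531
5x2cv text vs baseline: t = 16.94 (df=5), p = 0.0000
...
'schneid' (chatter): used in 518 chats; mirrored by the other channel in 0.67 of them
clustered 120 stems (0 without a vector) into k=20 clusters
```

Reading: the index consultations match the intended population moments
(≈25 chatter messages, ≈18 counselor messages, ≈456 words); the text
model reaches holdout AUROC 0.648, clearly above both chance
(permutation p = 0.001) and the conversation-length/daytime baseline
(0.531); the counselor mirrors a chatter's self-harm stem in two thirds
of the chats where it occurs, and the stem predictors group into 20
embedding clusters.

The same steps are available as a CLI (`rechat simulate / prepare /
tune / train / evaluate`) for arbitrary JSONL/CSV message exports.

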