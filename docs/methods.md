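# Methods

## Outcome construction

Messages of one chat are sorted by timestamp and partitioned greedily: a
new consultation starts whenever the silence since the previous message
is **≥ 6 hours** (the boundary gap itself splits; configurable). A
consultation *qualifies* as an actual counseling session with ≥ 3
counselor messages and ≥ 10 messages overall; the first qualifying
consultation is the **index**. The outcome is true iff any later
consultation containing at least one chatter message starts within **188
days (inclusive)** of the index's end. Because sessionization precedes
labeling, a follow-up inside six hours merges into the index and can
never count as recontact. Design choices where the procedure is
genuinely open, all configurable:

- a recontact consultation need not itself qualify — the chatter only
  has to contact the service again, not necessarily be counseled again;
- a purely counselor-initiated follow-up does not count;
- the chronological split is half-open: an index starting exactly at the
  cutoff belongs to the test set;
- records whose index ends less than 188 days before the corpus end are
  labeled from the data available (no censoring correction), matching a
  fixed-window reading applied to all chatters;
- earlier non-qualifying contacts are ignored for features and labels.

A sensitivity helper relabels the corpus at outcome windows 150–210 days
and reports the score spread; with most recontact delays inside the
first week the labeling barely moves (prevalence sd ≈ 0.001 on default
synthetic data).

## Anonymization

The privacy pipeline mirrors what a service can export without exposing
its users: whole-token case-insensitive replacement of listed names and
city names with `[NAME]`/`[CITY]`; lowercased whitespace tokenization
with flanking punctuation stripped (digits kept — a stated age is
predictive); a pluggable stemmer (identity by default, since the
synthetic lexicons are already stems); a seeded uniform shuffle of stems
within each speaker; and deletion of every stem present in fewer than 5
chats, counting both channels of a chat once. Pruning operates on the
full corpus before the train/test split — this mirrors an anonymization
step that necessarily precedes analysis, and constitutes a mild,
documented leak of document frequencies across the split; a train-only
mode is available.

## Features

Per chatter, the index consultation yields one chatter document and one
counselor document. Each channel has its own TF-IDF vectorizer: raw term
counts, optional smoothed IDF (`log((1+N)/(1+df)) + 1`), Euclidean
normalization per channel vector, and channel-specific df bounds —
`min_df` an absolute chat count, `max_df` a proportion. The two vectors
are concatenated with `CH:`/`CO:` column prefixes. Vectorizers are
always fitted inside the training portion of a fold, never on held-out
chats. Whether the term vectors should be normalized at all is not
canonical; the (most common) l2 convention is pinned in
`VectorizerParams` and reported with every model bundle. The metadata
baseline uses three columns: chatter word count, counselor word count,
and the integer clock hour of the index start (trees split ordinally, so
no cyclic encoding by default).

## Model and search

XGBoost with logistic objective, `hist` tree method, single thread, no
class reweighting, probabilities used raw at a 0.5 threshold. Boosting
rounds default to 500 with no early stopping and are excluded from the
search. The eleven searched grids (df bounds, IDF switch, `eta`,
`gamma`, `max_depth`, `min_child_weight`, `subsample`,
`colsample_bytree`) are optimized jointly by sequential model-based
optimization: configurations are encoded as grid indices scaled to
[0, 1], a Gaussian-process surrogate (Matérn 5/2 + white noise) is fit
to the observed CV scores, and the next configuration maximizes expected
improvement over a 256-point random candidate pool; the first quarter of
the budget is random exploration. Infeasible configurations (df bounds
that empty a vocabulary) score at chance level and are flagged in the
trace; the returned optimum is the best *feasible* configuration. The
objective is the mean AUROC of a repeated stratified k-fold CV (5×5 by
default; repeat r uses seed `base + r`). Everything is deterministic
given the seed.

## Significance testing

- **Corrected 5×2cv paired t-test** (text vs baseline): five seeded
  stratified 50/50 splits; both pipelines trained on each half and
  scored by AUROC difference on the other; with per-replication variance
  s²ᵢ = (dᵢ₁−d̄ᵢ)² + (dᵢ₂−d̄ᵢ)², the statistic t = d₁₁ / √(mean s²ᵢ) is
  referred two-sided to t(5). If every difference is zero, t = 0 and
  p = 1. The test is calibrated when the two pipelines differ only in
  training randomness; comparing structurally different feature sets on
  small noise datasets inflates it (chance dataset-level correlations
  persist across halves), which the test suite's null design respects.
- **Label-permutation test** of the holdout AUROC: labels are permuted
  against fixed predictions; because AUROC is a rank statistic the
  permuted scores are computed from fixed midranks, making the p value
  invariant to monotone transforms of the scores. Default 1,000
  permutations with add-one smoothing, so p is never exactly 0.

One inconsistency is enforced away rather than reproduced: with
recontact as the positive class, recall *is* sensitivity, and the
metrics report asserts that identity.

## Explainability

TreeSHAP attributions come from XGBoost's native `pred_contribs`
implementation (exact tree-path attribution); every report checks local
accuracy — base value plus attributions equals the margin within 1e-4 —
before anything is ranked. Context for single stems (unreadable after
shuffling, and n-grams are impossible by construction) comes from a
cross-channel co-occurrence table per target stem and from k-means
clustering of stem embeddings: for each k in a range (default 5–40) a
seeded k-means with 10 restarts is scored by mean silhouette (Euclidean
by default, cosine by flag); k is the silhouette argmax subject to an
optional usability floor, since a handful of huge clusters can score
well yet read poorly. Embeddings are pluggable: a word2vec-format text
file, or a corpus-trained count-based embedding (chat-level
co-occurrence → positive PMI → truncated SVD, default 50 dimensions).
The corpus-trained variant captures topical, not syntactic, similarity —
sufficient to group the generator's topic lexicons, coarser than large
pretrained vectors on real text.

## The synthetic corpus generator

The generator emulates the statistical structure the analysis assumes,
and is the ground-truth oracle for every downstream test:

- **Counts.** Chatter/counselor message counts are negative binomial
  (mean 25.4 / sd 20.8 and mean 17.7 / sd 12.1 — sd ≫ mean rules out
  Poisson), truncated to the qualification region (≥1 chatter message,
  ≥3 counselor, ≥10 total). The pre-truncation means are calibrated by
  an exact fixed-point computation on the truncated joint law so the
  *post*-qualification means hit the targets. Total words are negative
  binomial (mean 456.4, sd 283.9), resampled below the message count and
  above the 3,340-word cap.
- **Outcome.** Each chatter carries latent drivers — age (12–24,
  mean 17), gender (65% female), active topics (self-harm 0.25, suicide
  0.15, work 0.20, counselor redirection 0.30, emotional adjectives
  0.50), a nighttime start — entering a logistic model whose intercept
  is solved by exact enumeration + root-finding so the marginal
  prevalence is 0.431. Effect signs: young, female, self-harm, suicide,
  night positive; work, redirection, male negative. Magnitudes are
  generator defaults (≈0.5–0.9 in log-odds), chosen once so that the
  planted signal yields an oracle AUROC of ≈0.70 and a fitted holdout
  AUROC in the 0.65–0.75 band — the performance regime the method is
  meant to operate in.
- **Text.** Messages are stem sequences: a Zipf-weighted background
  lexicon plus, for each active topic, at least one forced stem from its
  lexicon (~4% of the channel's words); chatters state their age stem
  (p = 0.8) and a gender stem (p = 0.65). Lexicons are pairwise
  disjoint. The counselor *echoes* the distinct topic stems the chatter
  used with probability 2/3 per topic, and is the only speaker emitting
  redirection stems — so the cross-channel share of a mirrored stem
  estimates the mirroring probability directly.
- **Recontact delay.** A mixture with 0.55 mass uniform on 0.3–7 days
  (always exceeding the six-hour session threshold) and the rest on an
  exponential tail (scale 35 d) truncated at 188 days; only the
  early-mass constraint is prescribed by the population being emulated,
  the tail shape is a free modeling choice. Positives receive a short
  follow-up consultation after the sampled delay.
- **Timestamps.** First messages spread uniformly over Oct 2021–Dec
  2022 with an evening-peaked hour distribution, so the chronological
  split is exercisable; within a consultation gaps are uniform 0.5–20
  minutes.
- An optional flag emits a share of non-qualifying contacts (the
  excluded-chatter phenomenon); default off.

What the generator does **not** model: grammar or narrative order
(destroyed downstream anyway), counselor identity, seasonal or trend
effects, vocabulary drift between train and test periods, and
message-length dependence on content. Passing tests therefore show the
pipeline recovers planted word-level signal under the stated population
structure — not that comparable performance is attainable on any real
service's data.

## Problem sizes and numerical choices

The test suite and analysis drivers run scaled-down versions of the full
procedure, as deliberate package defaults: generator calibration at
n = 10,000; planted-signal recovery at n = 4,000 with an 8-iteration
search over 3-fold single-repeat CV and 150 boosting rounds; the 5×2cv
null calibration over 200 runs of n = 150; permutation-null uniformity
over 200 runs × 99 permutations. Full-scale settings (250 search
iterations, 5×5 CV, 500 rounds, 1,000 permutations) are one flag away in
`analysis/03_tune_train.py` and the library defaults. Other numerics:
intercept root-finding on [−10, 10] with xtol 1e-10 (no root raises a
configuration error); stratified folds are redrawn (up to 10 times) if a
test fold is single-class; SHAP local-accuracy tolerance 1e-4; k-means
ties broken by the first silhouette argmax; degenerate 5×2 denominators
yield t = 0, p = 1.

## Known limitations

Single-stem features only (no n-grams, by construction of the shuffled
input); no probability calibration; no censoring model for chatters
observed less than 188 days; the corpus-trained embeddings are weaker
than pretrained vectors; the ablation modes (chatter-only,
counselor-only, merged channels) are supported but ship without tuned
settings of their own.
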