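"""Boosted-tree pipelines, repeated CV and the SMBO hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

from rechat import modeling
from rechat.features import VectorizerParams
from rechat.modeling import (
    BoosterParams, PipelineParams, TextPipeline, bayes_search, cv_evaluate,
)

LOOSE_VEC = VectorizerParams(
    min_df_chatter=1, min_df_couns=1, max_df_chatter=1.0, max_df_couns=1.0
)
SMALL_BOOST = BoosterParams(eta=0.3, gamma=0.0, max_depth=3, min_child_weight=1,
                            subsample=1.0, colsample_bytree=1.0, n_rounds=40)
SMALL_PARAMS = PipelineParams(vec=LOOSE_VEC, booster=SMALL_BOOST)


def planted_dataset(n=300, seed=0, signal="sig", noise_vocab=8):
    """Docs where the positive class always carries a marker stem."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.45
    vocab = [f"w{i}" for i in range(noise_vocab)]
    ch = [
        " ".join(list(rng.choice(vocab, size=10)) + ([signal] * 3 if yi else []))
        for yi in y
    ]
    co = [" ".join(rng.choice(vocab, size=6)) for _ in range(n)]
    return pd.DataFrame({"chatter_doc": ch, "counselor_doc": co}), y.astype(int)


def factory(params=SMALL_PARAMS, seed=0):
    return lambda: TextPipeline(params, seed=seed)


class TestCvEvaluate:
    def test_returns_5x5_scores(self):
        ds, y = planted_dataset()
        rep = cv_evaluate(factory(), ds, y, seed=1)
        assert rep.scores.shape == (5, 5)
        assert rep.scores.min() <= rep.mean <= rep.scores.max()

    def test_separable_data_scores_near_one(self):
        ds, y = planted_dataset()
        rep = cv_evaluate(factory(), ds, y, n_folds=3, n_repeats=1, seed=0)
        assert rep.mean > 0.97

    def test_shuffled_labels_score_near_chance(self):
        ds, y = planted_dataset(n=400)
        y_perm = np.random.default_rng(7).permutation(y)
        rep = cv_evaluate(factory(), ds, y_perm, n_folds=3, n_repeats=2, seed=0)
        assert abs(rep.mean - 0.5) < 0.08

    def test_single_class_rejected(self):
        ds, y = planted_dataset(n=50)
        with pytest.raises(ValueError, match="classes"):
            cv_evaluate(factory(), ds, np.zeros(50, dtype=int))

    def test_fold_hygiene_vocabulary_excludes_held_out_stems(self):
        """A stem unique to held-out docs never enters the fitted vocabulary."""
        ds, y = planted_dataset(n=60, seed=2)
        ds = ds.copy()
        ds["chatter_doc"] = [
            f"{doc} unique{i}" for i, doc in enumerate(ds["chatter_doc"])
        ]
        seen = []

        class Spy(TextPipeline):
            def fit(self, dataset, yy):
                out = super().fit(dataset, yy)
                seen.append(
                    (set(dataset.index), set(self.vectorizer.feature_names))
                )
                return out

        cv_evaluate(lambda: Spy(SMALL_PARAMS), ds, y, n_folds=3, n_repeats=1, seed=0)
        for train_idx, vocab in seen:
            held_out = set(range(60)) - train_idx
            for i in held_out:
                assert f"CH:unique{i}" not in vocab


class TestBayesSearch:
    def test_single_iteration_returns_evaluated_config(self):
        ds, y = planted_dataset(n=120)
        best, trace = bayes_search(
            ds, y, n_iter=1, seed=0, n_folds=2, n_repeats=1, n_rounds=20
        )
        assert len(trace) == 1
        row = trace.iloc[0]
        assert best.booster.eta == row["eta"]
        assert best.vec.use_idf == row["use_idf"]

    def test_degenerate_space_returns_that_config(self):
        ds, y = planted_dataset(n=120)
        space = {k: [v[0]] for k, v in modeling.TABLE2_GRIDS.items()}
        space["min_df_chatter"] = [1]
        space["min_df_couns"] = [1]
        space["max_df_chatter"] = [1.0]
        space["max_df_couns"] = [1.0]
        best, trace = bayes_search(
            ds, y, space=space, n_iter=2, seed=0, n_folds=2, n_repeats=1,
            n_rounds=20,
        )
        assert best.booster.eta == 0.005
        assert best.vec.min_df_chatter == 1

    def test_recovers_dominant_df_setting_vs_exhaustive_oracle(self):
        """On data where the signal stem is rare, a small min_df strictly
        dominates; the search recovers the exhaustive argmax."""
        ds, y = planted_dataset(n=240, seed=5)
        space = {"min_df_chatter": [1, 200], "use_idf": [True, False]}
        kw = dict(n_folds=2, n_repeats=1)

        def score(cfg):
            params = modeling.params_from_mapping(
                {**{k: g[0] for k, g in modeling.TABLE2_GRIDS.items()},
                 "min_df_chatter": cfg[0], "use_idf": cfg[1],
                 "max_df_chatter": 1.0, "max_df_couns": 1.0, "min_df_couns": 1,
                 "eta": 0.3, "gamma": 0, "max_depth": 4, "min_child_weight": 1,
                 "subsample": 1.0, "colsample_bytree": 1.0},
                n_rounds=20,
            )
            try:
                return cv_evaluate(
                    lambda: TextPipeline(params, seed=0), ds, y, seed=0, **kw
                ).mean
            except ValueError:
                return 0.5

        exhaustive = {
            (mdf, idf): score((mdf, idf))
            for mdf in space["min_df_chatter"] for idf in space["use_idf"]
        }
        best_cfg = max(exhaustive, key=exhaustive.get)
        assert best_cfg[0] == 1  # min_df=200 removes the signal stem

        full_space = {
            **{k: [g[0]] for k, g in modeling.TABLE2_GRIDS.items()},
            "min_df_chatter": space["min_df_chatter"],
            "use_idf": space["use_idf"],
            "max_df_chatter": [1.0], "max_df_couns": [1.0], "min_df_couns": [1],
            "eta": [0.3], "gamma": [0], "max_depth": [4],
            "min_child_weight": [1], "subsample": [1.0],
            "colsample_bytree": [1.0],
        }
        best, trace = bayes_search(
            ds, y, space=full_space, n_iter=4, seed=3, n_rounds=20, **kw
        )
        assert best.vec.min_df_chatter == 1

    def test_trace_scores_reproducible(self):
        ds, y = planted_dataset(n=150)
        best, trace = bayes_search(
            ds, y, n_iter=3, seed=9, n_folds=2, n_repeats=1, n_rounds=20
        )
        top = trace.loc[trace.score.idxmax()]
        re_run = cv_evaluate(
            lambda: TextPipeline(best, seed=9), ds, y,
            n_folds=2, n_repeats=1, seed=9,
        )
        assert re_run.mean == pytest.approx(top["score"], abs=1e-12)

    def test_zero_iterations_rejected(self):
        ds, y = planted_dataset(n=50)
        with pytest.raises(ValueError):
            bayes_search(ds, y, n_iter=0)


class TestFinalFit:
    def test_save_load_round_trip_identical_predictions(self, tmp_path):
        ds, y = planted_dataset(n=200)
        pipe = modeling.fit_final(ds, y, SMALL_PARAMS, seed=4)
        pipe.save(tmp_path / "bundle")
        back = TextPipeline.load(tmp_path / "bundle")
        p1 = pipe.predict_proba(ds)
        p2 = back.predict_proba(ds)
        assert np.array_equal(p1, p2)

    def test_planted_positive_stem_raises_probability(self):
        ds, y = planted_dataset(n=300)
        pipe = modeling.fit_final(ds, y, SMALL_PARAMS, seed=0)
        neutral = pd.DataFrame(
            {"chatter_doc": ["w0 w1 w2 w3"], "counselor_doc": ["w0"]}
        )
        loaded = pd.DataFrame(
            {"chatter_doc": ["w0 w1 w2 w3 sig sig sig sig"], "counselor_doc": ["w0"]}
        )
        assert pipe.predict_proba(loaded)[0] > pipe.predict_proba(neutral)[0]
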