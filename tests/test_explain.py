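"""SHAP attributions, co-occurrence context and embedding clustering."""

import numpy as np
import pandas as pd
import pytest

from rechat import explain, modeling
from rechat.features import VectorizerParams
from rechat.modeling import BoosterParams, PipelineParams, TextPipeline

LOOSE = PipelineParams(
    vec=VectorizerParams(min_df_chatter=1, min_df_couns=1,
                         max_df_chatter=1.0, max_df_couns=1.0),
    booster=BoosterParams(eta=0.3, gamma=0.0, max_depth=3, min_child_weight=1,
                          subsample=1.0, colsample_bytree=1.0, n_rounds=30),
)


class TestShap:
    def _fit(self, ds, y, **boost_kw):
        params = LOOSE
        if boost_kw:
            params = PipelineParams(
                vec=LOOSE.vec, booster=BoosterParams(**{**LOOSE.booster.__dict__,
                                                        **boost_kw})
            )
        return TextPipeline(params, seed=0).fit(ds, y)

    def test_single_stump_attribution_is_margin_minus_base(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        ds = pd.DataFrame(
            {
                "chatter_doc": ["sig" if yi else "blank" for yi in y],
                "counselor_doc": ["x"] * 200,
            }
        )
        pipe = self._fit(ds, y, n_rounds=1, max_depth=1)
        rep = explain.shap_attribution(pipe, ds)
        # a single tree on effectively one informative feature: the signal
        # column carries the entire margin offset
        recon = rep.base_value + rep.attributions.sum(axis=1)
        assert np.allclose(recon, rep.margins, atol=1e-5)

    def test_local_accuracy_on_fitted_pipeline(self, small_dataset):
        ds = small_dataset
        y = ds.label.to_numpy(dtype=int)
        pipe = self._fit(ds, y)
        rep = explain.shap_attribution(pipe, ds)
        assert rep.additivity_gap() < 1e-4
        assert rep.attributions.shape[1] == len(pipe.feature_names)

    def test_channel_feature_counts(self, small_dataset):
        ds = small_dataset
        pipe = self._fit(ds, ds.label.to_numpy(dtype=int))
        rep = explain.shap_attribution(pipe, ds)
        n_ch, n_co = pipe.vectorizer.n_features
        assert rep.n_features_per_channel == {"chatter": n_ch, "counselor": n_co}


class TestCooccurrence:
    toy = pd.DataFrame(
        {
            "chatter_doc": ["a b suizid", "suizid gedank", "b c"],
            "counselor_doc": ["x suizid", "y gedank", "z"],
        }
    )

    def test_manual_tally(self):
        t = explain.cooccurrence(self.toy, "suizid", "chatter")
        assert t.n_target_chats == 2
        # counselor stems across the two suizid-chats
        assert t.counts.to_dict() == {"x": 1, "suizid": 1, "y": 1, "gedank": 1}
        assert t.cross_channel_share == 0.5
        assert (t.share <= 1).all()

    def test_absent_target_is_empty(self):
        t = explain.cooccurrence(self.toy, "nichtda", "chatter")
        assert t.n_target_chats == 0 and t.counts.empty

    def test_bad_channel_rejected(self):
        with pytest.raises(ValueError):
            explain.cooccurrence(self.toy, "a", "therapist")


class TestEmbeddings:
    def test_word2vec_text_loader(self, tmp_path):
        p = tmp_path / "vecs.txt"
        p.write_text("2 3\nhaus 1.0 0.0 0.5\narbeit 0.0 1.0 -0.5\n")
        vecs = explain.load_word2vec_text(p)
        assert set(vecs) == {"haus", "arbeit"}
        assert vecs["haus"].tolist() == [1.0, 0.0, 0.5]
        # headerless variant
        q = tmp_path / "plain.txt"
        q.write_text("haus 1 0\narbeit 0 1\n")
        assert explain.load_word2vec_text(q)["arbeit"].tolist() == [0.0, 1.0]

    def test_ppmi_svd_groups_cooccurring_stems(self):
        rng = np.random.default_rng(0)
        docs = []
        for _ in range(120):
            if rng.random() < 0.5:
                docs.append(list(rng.choice(["arbeit", "job", "chef"], 6)) + ["und"])
            else:
                docs.append(list(rng.choice(["nacht", "schlaf", "spat"], 6)) + ["und"])
        emb = explain.PpmiSvdEmbeddings(dim=4, seed=0).fit(docs)
        def d(a, b):
            return np.linalg.norm(emb[a] - emb[b])
        assert d("arbeit", "job") < d("arbeit", "nacht")
        assert d("nacht", "schlaf") < d("nacht", "chef")


class TestEmbedCluster:
    def _provider(self, rng, centers, n_per=12):
        vecs = {}
        for c, center in enumerate(centers):
            for i in range(n_per):
                vecs[f"s{c}_{i}"] = center + rng.normal(0, 0.05, size=len(center))
        return vecs

    def test_two_separated_clouds_choose_k2(self):
        rng = np.random.default_rng(1)
        vecs = self._provider(rng, [np.array([0.0, 0.0]), np.array([5.0, 5.0])])
        stems = list(vecs)
        imp = pd.Series(1.0, index=stems)
        rep = explain.embed_cluster(stems, imp, vecs, k_range=range(2, 7), seed=0)
        assert rep.k == 2
        assert rep.silhouette_by_k[2] > 0.9

    def test_importance_conservation(self):
        rng = np.random.default_rng(2)
        vecs = self._provider(
            rng, [np.zeros(3), np.full(3, 4.0), np.array([0, 5.0, 0])]
        )
        stems = list(vecs)
        imp = pd.Series(rng.random(len(stems)), index=stems)
        rep = explain.embed_cluster(stems, imp, vecs, k_range=range(2, 8), seed=0)
        assert rep.cluster_importance.sum() == pytest.approx(imp.sum())
        assert rep.cluster_sizes.sum() == rep.n_embedded

    def test_missing_stems_counted_not_clustered(self):
        rng = np.random.default_rng(3)
        vecs = self._provider(rng, [np.zeros(2), np.full(2, 3.0)])
        stems = list(vecs) + ["fehlt1", "fehlt2"]
        imp = pd.Series(1.0, index=stems)
        rep = explain.embed_cluster(stems, imp, vecs, k_range=range(2, 5), seed=0)
        assert rep.n_missing == 2
        assert "fehlt1" not in rep.assignments.index

    def test_min_k_usability_floor(self):
        rng = np.random.default_rng(1)
        vecs = self._provider(rng, [np.array([0.0, 0.0]), np.array([5.0, 5.0])])
        stems = list(vecs)
        imp = pd.Series(1.0, index=stems)
        rep = explain.embed_cluster(
            stems, imp, vecs, k_range=range(2, 8), seed=0, min_k=4
        )
        assert rep.k >= 4

    def test_too_few_embeddable_stems_raises(self):
        with pytest.raises(ValueError, match="embeddable"):
            explain.embed_cluster(
                ["a", "b"], pd.Series(1.0, index=["a", "b"]),
                {"a": np.zeros(2)}, k_range=range(2, 5),
            )

    def test_kmeans_matches_seeded_lloyd_rerun(self):
        """sklearn's assignment equals a hand-coded Lloyd iteration from the
        same initial centers on a 20-point toy set."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(8, 1, (10, 2))])
        init = X[[0, 10]]
        km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=100).fit(X)

        centers = init.copy()
        for _ in range(100):
            d = np.linalg.norm(X[:, None, :] - centers[None], axis=2)
            lab = d.argmin(axis=1)
            new = np.vstack([X[lab == j].mean(axis=0) for j in range(2)])
            if np.allclose(new, centers):
                break
            centers = new
        assert np.array_equal(km.labels_, lab) or np.array_equal(
            km.labels_, 1 - lab
        )
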