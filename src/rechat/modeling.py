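"""Gradient-boosted classification, repeated cross-validation and
joint Bayesian hyperparameter search.

The classifier is XGBoost with a logistic objective, fed by the
concatenated dual-channel TF-IDF matrix (text pipeline) or by the
word-count + hour-of-day matrix (metadata baseline). All eleven
hyperparameters — the four document-frequency bounds, the IDF switch and
the six booster parameters — are tuned jointly over their discrete grids
by sequential model-based optimization (Gaussian-process surrogate,
expected-improvement acquisition, integer-coded grid coordinates),
maximizing the mean AUROC of a repeated stratified k-fold CV. Class
imbalance is left unweighted and probabilities are used raw.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .features import BASELINE_COLUMNS, DualVectorizer, VectorizerParams, baseline_matrix

__all__ = [
    "BoosterParams",
    "PipelineParams",
    "TABLE2_GRIDS",
    "BEST_PARAMS_FULL_SCALE",
    "TextPipeline",
    "BaselinePipeline",
    "CVReport",
    "cv_evaluate",
    "bayes_search",
    "fit_final",
]


@dataclass(frozen=True)
class BoosterParams:
    """XGBoost hyperparameters exposed to the search.

    Defaults are the best full-scale configuration of the text model.
    `n_rounds` (boosting rounds, no early stopping) is not searched.
    """

    eta: float = 0.05
    gamma: float = 1.5
    max_depth: int = 8
    min_child_weight: float = 20
    subsample: float = 0.6
    colsample_bytree: float = 0.9
    n_rounds: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.subsample <= 1 and 0 < self.colsample_bytree <= 1):
            raise ValueError("subsample/colsample_bytree must lie in (0, 1]")


@dataclass(frozen=True)
class PipelineParams:
    """Joint vectorizer + booster configuration of the text pipeline."""

    vec: VectorizerParams = field(default_factory=VectorizerParams)
    booster: BoosterParams = field(default_factory=BoosterParams)


#: The eleven tunable-hyperparameter grids searched jointly.
TABLE2_GRIDS: dict[str, list] = {
    "max_df_chatter": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "min_df_chatter": [1, 2, 5, 10, 25, 50, 75, 100, 150, 200],
    "max_df_couns": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "min_df_couns": [1, 2, 5, 10, 25, 50, 75, 100, 150, 200],
    "use_idf": [True, False],
    "colsample_bytree": [0.2, 0.4, 0.6, 0.7, 0.8, 0.9, 1.0],
    "eta": [0.005, 0.01, 0.05, 0.1, 0.2],
    "gamma": [0, 0.25, 0.5, 1, 1.5, 2, 5, 10],
    "max_depth": [2, 4, 6, 8, 10, 12, 14, 16],
    "min_child_weight": [1, 5, 10, 20],
    "subsample": [0.2, 0.4, 0.6, 0.7, 0.8, 0.9, 1.0],
}

_VEC_KEYS = ("max_df_chatter", "min_df_chatter", "max_df_couns", "min_df_couns", "use_idf")

#: Best joint configuration of the full-scale search (text model).
BEST_PARAMS_FULL_SCALE = PipelineParams()


def params_from_mapping(cfg: dict, n_rounds: int = 500) -> PipelineParams:
    vec = VectorizerParams(**{k: cfg[k] for k in _VEC_KEYS})
    booster = BoosterParams(
        n_rounds=n_rounds, **{k: cfg[k] for k in TABLE2_GRIDS if k not in _VEC_KEYS}
    )
    return PipelineParams(vec=vec, booster=booster)


def _make_xgb(booster: BoosterParams, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=booster.n_rounds,
        learning_rate=booster.eta,
        gamma=booster.gamma,
        max_depth=booster.max_depth,
        min_child_weight=booster.min_child_weight,
        subsample=booster.subsample,
        colsample_bytree=booster.colsample_bytree,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


class TextPipeline:
    """Dual-channel TF-IDF + XGBoost text classifier."""

    def __init__(self, params: PipelineParams | None = None, seed: int = 0) -> None:
        self.params = params or PipelineParams()
        self.seed = seed
        self.vectorizer = DualVectorizer(self.params.vec)
        self.model = _make_xgb(self.params.booster, seed)

    def fit(self, dataset: pd.DataFrame, y: np.ndarray) -> "TextPipeline":
        X = self.vectorizer.fit_transform(
            dataset["chatter_doc"], dataset["counselor_doc"]
        )
        self.model.fit(X, np.asarray(y, dtype=int))
        return self

    def design_matrix(self, dataset: pd.DataFrame) -> sp.csr_matrix:
        return self.vectorizer.transform(
            dataset["chatter_doc"], dataset["counselor_doc"]
        )

    def predict_proba(self, dataset: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(self.design_matrix(dataset))[:, 1]

    @property
    def feature_names(self) -> list[str]:
        return self.vectorizer.feature_names

    # --- persistence ------------------------------------------------------

    def save(self, bundle_dir: str | Path) -> None:
        d = Path(bundle_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.vectorizer.to_json(d / "vectorizer.json")
        self.model.get_booster().save_model(d / "booster.json")
        (d / "params.yaml").write_text(
            yaml.safe_dump({"vec": asdict(self.params.vec),
                            "booster": asdict(self.params.booster),
                            "seed": self.seed})
        )

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "TextPipeline":
        d = Path(bundle_dir)
        meta = yaml.safe_load((d / "params.yaml").read_text())
        params = PipelineParams(
            vec=VectorizerParams(**meta["vec"]), booster=BoosterParams(**meta["booster"])
        )
        self = cls(params, seed=meta.get("seed", 0))
        self.vectorizer = DualVectorizer.from_json(d / "vectorizer.json")
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(str(d / "booster.json"))
        self.model._Booster = booster
        self.model.n_classes_ = 2
        return self


class BaselinePipeline:
    """XGBoost on the metadata features only (word counts + hour of day)."""

    def __init__(self, booster: BoosterParams | None = None, seed: int = 0) -> None:
        # full-scale best baseline configuration
        self.booster = booster or BoosterParams(
            eta=0.01, gamma=0.25, max_depth=6, min_child_weight=10,
            subsample=0.8, colsample_bytree=0.8, n_rounds=500,
        )
        self.seed = seed
        self.model = _make_xgb(self.booster, seed)

    def fit(self, dataset: pd.DataFrame, y: np.ndarray) -> "BaselinePipeline":
        self.model.fit(baseline_matrix(dataset), np.asarray(y, dtype=int))
        return self

    def predict_proba(self, dataset: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(baseline_matrix(dataset))[:, 1]

    @property
    def feature_names(self) -> list[str]:
        return list(BASELINE_COLUMNS)


@dataclass
class CVReport:
    """All fold scores of a repeated CV plus the evaluated configuration."""

    scores: np.ndarray  # shape (n_repeats, n_folds)
    params: object

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))


def cv_evaluate(
    pipeline_factory,
    dataset: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    params: object = None,
) -> CVReport:
    """Repeated stratified k-fold AUROC of a pipeline factory.

    Every repeat draws a fresh seeded stratified fold assignment (repeat r
    uses seed ``seed + r``); per fold the pipeline (vectorizer included) is
    fitted on the training portion only. Returns all ``n_repeats x
    n_folds`` scores.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("cv_evaluate needs both classes present")
    dataset = dataset.reset_index(drop=True)
    scores = np.empty((n_repeats, n_folds))
    for r in range(n_repeats):
        folds = _stratified_folds(y, n_folds, seed + r)
        for f, (tr, te) in enumerate(folds):
            pipe = pipeline_factory()
            pipe.fit(dataset.iloc[tr], y[tr])
            scores[r, f] = roc_auc_score(y[te], pipe.predict_proba(dataset.iloc[te]))
    return CVReport(scores=scores, params=params)


def _stratified_folds(y, n_folds, seed, max_tries=10):
    for attempt in range(max_tries):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 for _, te in folds):
            return folds
    raise ValueError("could not build folds with both classes in every test fold")


# ---------------------------------------------------------------------------
# sequential model-based optimization over the discrete grids


def _encode(cfg: dict, space: dict[str, list]) -> np.ndarray:
    """Grid-index coordinates scaled to [0, 1] per dimension."""
    x = np.empty(len(space))
    for j, (k, grid) in enumerate(space.items()):
        i = grid.index(cfg[k])
        x[j] = i / (len(grid) - 1) if len(grid) > 1 else 0.0
    return x


def _random_config(rng: np.random.Generator, space: dict[str, list]) -> dict:
    return {k: grid[rng.integers(len(grid))] for k, grid in space.items()}


def bayes_search(
    dataset: pd.DataFrame,
    y: np.ndarray,
    space: dict[str, list] | None = None,
    n_iter: int = 250,
    seed: int = 0,
    n_folds: int = 5,
    n_repeats: int = 5,
    n_rounds: int = 500,
    pipeline_factory=None,
) -> tuple[PipelineParams, pd.DataFrame]:
    """Jointly tune all grid hyperparameters by SMBO, maximizing CV AUROC.

    A Gaussian-process surrogate over the integer-coded grids proposes the
    next configuration by expected improvement among a random candidate
    pool; the first quarter of the budget is random exploration.
    Infeasible configurations (document-frequency bounds that empty a
    vocabulary) score at chance and are marked in the trace. Deterministic
    given ``seed``. Returns the best configuration and the full trace.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = dict(space if space is not None else TABLE2_GRIDS)
    make = pipeline_factory or (
        lambda params, s: TextPipeline(params, seed=s)
    )
    rng = np.random.default_rng(seed)
    evaluated: list[dict] = []
    xs: list[np.ndarray] = []
    ys: list[float] = []
    trace_rows: list[dict] = []
    n_init = max(min(5, n_iter), n_iter // 4)
    seen: set[tuple] = set()

    def propose() -> dict:
        if len(evaluated) < n_init or len(ys) < 2:
            return _random_config(rng, space)
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5)
            + WhiteKernel(1e-3),
            normalize_y=True,
            alpha=1e-8,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.vstack(xs), np.asarray(ys))
        cands = [_random_config(rng, space) for _ in range(256)]
        cands = [c for c in cands if tuple(sorted(c.items())) not in seen] or cands
        X = np.vstack([_encode(c, space) for c in cands])
        mu, sd = gp.predict(X, return_std=True)
        best = max(ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sd
            ei = np.where(sd > 0, (mu - best) * stats.norm.cdf(z) + sd * stats.norm.pdf(z), 0.0)
        return cands[int(np.argmax(ei))]

    for it in range(n_iter):
        cfg = propose()
        params = params_from_mapping({**_defaults_for(space), **cfg}, n_rounds=n_rounds)
        try:
            report = cv_evaluate(
                lambda: make(params, seed),
                dataset, y, n_folds=n_folds, n_repeats=n_repeats, seed=seed,
                params=params,
            )
            score, feasible = report.mean, True
        except ValueError:
            score, feasible = 0.5, False
        evaluated.append(cfg)
        seen.add(tuple(sorted(cfg.items())))
        xs.append(_encode(cfg, space))
        ys.append(score)
        trace_rows.append({**cfg, "score": score, "feasible": feasible, "iteration": it})

    trace = pd.DataFrame(trace_rows)
    feasible = trace["feasible"].to_numpy()
    scores = np.asarray(ys)
    if feasible.any():  # never return an untrainable configuration
        best_i = int(np.flatnonzero(feasible)[scores[feasible].argmax()])
    else:
        best_i = int(scores.argmax())
    best = params_from_mapping(
        {**_defaults_for(space), **evaluated[best_i]}, n_rounds=n_rounds
    )
    return best, trace


def _defaults_for(space: dict[str, list]) -> dict:
    """Fill grid keys missing from a reduced search space with defaults."""
    base = {**asdict(VectorizerParams()), **asdict(BoosterParams())}
    base.pop("n_rounds")
    return {k: base[k] for k in TABLE2_GRIDS}


def fit_final(
    dataset: pd.DataFrame, y: np.ndarray, params: PipelineParams, seed: int = 0
) -> TextPipeline:
    """Fit the text pipeline on the whole train set with fixed parameters."""
    return TextPipeline(params, seed=seed).fit(dataset, y)
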