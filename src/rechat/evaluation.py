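"""Holdout metrics, the corrected 5x2cv paired comparison and the
label-permutation significance test.

The 5x2cv test follows the classical corrected construction: five
replications of a stratified 50/50 split, both pipelines trained on each
half and scored (AUROC difference) on the other; the statistic is the
first replication's first-half difference divided by the root mean of the
per-replication difference variances, referred to a t distribution with 5
degrees of freedom, two-sided.

The permutation test keeps the holdout predictions fixed and shuffles the
labels; because AUROC is a rank statistic, every permuted score is
computed from the fixed midranks of the probabilities, which makes the
test invariant to monotone transforms of the scores and fast enough for
thousands of permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvalReport",
    "PairedTestResult",
    "PermutationResult",
    "metrics_report",
    "paired_5x2cv_test",
    "permutation_test",
]


@dataclass
class EvalReport:
    """Threshold metrics plus AUROC for one set of holdout predictions."""

    auroc: float | None
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation form: two decimals, like the study report tables."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def metrics_report(
    labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """All holdout metrics at a probability threshold.

    AUROC uses the rank statistic with tie midranks; when only one class is
    present it is reported as None while the threshold metrics remain
    defined (with empty-denominator rates reported as 0).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    auroc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else None
    return EvalReport(
        auroc=auroc,
        accuracy=(tp + tn) / n,
        balanced_accuracy=(sens + spec) / 2.0,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=sens,  # recall of the positive (recontact) class IS sensitivity
        sensitivity=sens,
        specificity=spec,
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    differences: np.ndarray  # shape (5, 2): per replication, per half


def paired_5x2cv_test(
    factory_a,
    factory_b,
    dataset: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    metric=roc_auc_score,
) -> PairedTestResult:
    """Corrected 5x2cv paired t-test between two pipeline factories.

    ``factory_a`` / ``factory_b`` build fresh unfitted pipelines with
    ``fit(dataset, y)`` and ``predict_proba(dataset)``. The comparison
    metric defaults to AUROC, the quantity both pipelines optimize.
    """
    y = np.asarray(y, dtype=int)
    dataset = dataset.reset_index(drop=True)
    d = np.empty((5, 2))
    for rep in range(5):
        half_a, half_b = _stratified_halves(y, seed + rep)
        for j, (tr, te) in enumerate(((half_a, half_b), (half_b, half_a))):
            pa = factory_a()
            pb = factory_b()
            pa.fit(dataset.iloc[tr], y[tr])
            pb.fit(dataset.iloc[tr], y[tr])
            sa = metric(y[te], pa.predict_proba(dataset.iloc[te]))
            sb = metric(y[te], pb.predict_proba(dataset.iloc[te]))
            d[rep, j] = sa - sb
    dbar = d.mean(axis=1)
    s2 = ((d[:, 0] - dbar) ** 2) + ((d[:, 1] - dbar) ** 2)
    denom = np.sqrt(s2.mean())
    if denom == 0.0:
        t = 0.0 if d[0, 0] == 0.0 else np.inf * np.sign(d[0, 0])
    else:
        t = d[0, 0] / denom
    p = 1.0 if t == 0.0 else float(2.0 * stats.t.sf(abs(t), df=5))
    return PairedTestResult(t=float(t), df=5, p=min(p, 1.0), differences=d)


def _stratified_halves(y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One seeded stratified 50/50 split."""
    rng = np.random.default_rng(seed)
    half_a, half_b = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = len(idx) // 2
        half_a.append(idx[:k])
        half_b.append(idx[k:])
    return np.sort(np.concatenate(half_a)), np.sort(np.concatenate(half_b))


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    permuted: np.ndarray
    p: float


def permutation_test(
    labels: np.ndarray,
    probabilities: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of the holdout AUROC.

    p = (1 + #{permuted >= observed}) / (1 + n_perm) — add-one smoothed so
    the p value is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(p)  # midranks; fixed across permutations
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("permutation test needs both classes")

    def auroc_from_positives(pos_idx: np.ndarray) -> float:
        return (ranks[pos_idx].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    observed = auroc_from_positives(np.flatnonzero(y == 1))
    permuted = np.empty(n_perm)
    idx = np.arange(len(y))
    for i in range(n_perm):
        perm = rng.permutation(idx)[:n1]
        permuted[i] = auroc_from_positives(perm)
    pval = (1.0 + (permuted >= observed).sum()) / (1.0 + n_perm)
    return PermutationResult(
        observed=float(observed), n_perm=n_perm, permuted=permuted, p=float(pval)
    )
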