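#!/usr/bin/env python
"""One-time evaluation on the chronological holdout.

Scores the trained text model on the newest consultations, reports the
threshold metrics and confusion counts, tests the AUROC against chance
by label permutation, and compares the text model against the
word-count + hour-of-day baseline with the corrected 5x2cv paired t-test
on the train split.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np

from rechat import evaluation, modeling

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "tune_train", Path(__file__).parent / "03_tune_train.py"
)
_tt = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_tt)


def main() -> None:
    test, y_test = _tt.load_dataset("test")
    train, y_train = _tt.load_dataset("train")
    pipe = modeling.TextPipeline.load(ROOT / "scratch" / "model")
    probs = pipe.predict_proba(test)

    report = evaluation.metrics_report(y_test, probs, threshold=0.5)
    perm = evaluation.permutation_test(y_test, probs, n_perm=1000, seed=5)
    print(f"holdout n={report.n}: AUROC {report.auroc:.3f} "
          f"(permutation p = {perm.p:.4f})")
    print(f"accuracy {report.accuracy:.2f}  balanced {report.balanced_accuracy:.2f}  "
          f"precision {report.precision:.2f}  recall {report.recall:.2f}")
    print(f"confusion: TP={report.tp} FP={report.fp} TN={report.tn} FN={report.fn}")

    baseline = modeling.BaselinePipeline(seed=5).fit(train, y_train)
    base_auc = evaluation.metrics_report(
        y_test, baseline.predict_proba(test)
    ).auroc
    print(f"metadata baseline holdout AUROC {base_auc:.3f}")

    res = evaluation.paired_5x2cv_test(
        lambda: modeling.TextPipeline(pipe.params, seed=5),
        lambda: modeling.BaselinePipeline(seed=5),
        train, y_train, seed=5,
    )
    print(f"5x2cv text vs baseline: t = {res.t:.2f} (df={res.df}), p = {res.p:.4f}")

    out = report.rounded()
    out["permutation_p"] = perm.p
    out["baseline_auroc"] = round(base_auc, 3)
    out["paired_5x2_t"] = round(res.t, 3)
    out["paired_5x2_p"] = round(res.p, 5)
    (ROOT / "results" / "holdout_metrics.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )

    # ROC curve points for plotting
    order = np.argsort(-probs)
    tps = np.cumsum(y_test[order])
    fps = np.cumsum(~y_test[order])
    with open(ROOT / "results" / "roc_points.csv", "w") as fh:
        fh.write("fpr,tpr\n")
        for f, t in zip(fps / fps[-1], tps / tps[-1]):
            fh.write(f"{f:.5f},{t:.5f}\n")


if __name__ == "__main__":
    main()
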