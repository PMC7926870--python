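#!/usr/bin/env python
"""AdaBoost baseline on principal components of first-derivative spectra.

Leave-one-out cross-validation of boosted decision stumps on the leading
principal components, with PCA refit inside every training fold.  Writes
results/ml_confusion.json.
"""

import json
from pathlib import Path

import numpy as np

from leukoftir.core import load_cohort
from leukoftir.evaluate import loocv_adaboost
from leukoftir.preprocess import preprocess_cohort, sg_derivative

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    cohort = preprocess_cohort(load_cohort(ROOT / "cohort" / "manifest.csv"))
    X = np.vstack([sg_derivative(s, 1).absorbance for s in cohort])
    y = np.array([1 if s.group == "bcp_all" else 0 for s in cohort])
    cm = loocv_adaboost(X, y, seed=SEED)
    block = {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
             "accuracy": cm.accuracy, "n_components": 5, "n_estimators": 50}
    (ROOT / "ml_confusion.json").write_text(json.dumps(block, indent=2, sort_keys=True))
    print(f"LOOCV confusion matrix: tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}")
    print(f"accuracy: {100 * cm.accuracy:.0f}%")


if __name__ == "__main__":
    main()
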