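"""ROC curve, AUC significance and operating-point metrics for the best model.

Reads the per-sample replication scores written by 03_fit_ladder.py, writes
the ROC curve points to results/roc.tsv, and prints the AUC with its
standard error and p-value against chance, plus predictive values at a
high-specificity operating point (sensitivity 0.2, specificity 0.95) under
the cohort's 30% exacerbation prevalence.
"""

from pathlib import Path

import pandas as pd

from exacerf import auc, operating_point, roc_curve

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scores = pd.read_csv(ROOT / "scores_best.tsv", sep="\t")
    result = auc(scores["score"], scores["label"])
    curve = roc_curve(scores["score"], scores["label"])
    pd.DataFrame(
        {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(ROOT / "roc.tsv", sep="\t", index=False)
    print(
        f"replication AUC = {result.auc:.3f} (SE {result.se:.3f}), "
        f"p vs 0.5 = {result.p_value:.4g} "
        f"({result.n_cases} cases / {result.n_controls} controls)"
    )
    op = operating_point(sensitivity=0.2, specificity=0.95, prevalence=0.3)
    print(
        f"at sens 0.20 / spec 0.95, prevalence 0.30: "
        f"PPV = {op.ppv:.2f}, NPV = {op.npv:.2f}"
    )
    print(f"ROC curve -> {ROOT / 'roc.tsv'}")


if __name__ == "__main__":
    main()
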