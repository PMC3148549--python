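"""ROC/AUC evaluation, AUC significance versus chance, and operating points.

The AUC is computed as the Mann-Whitney rank statistic
P(score_case > score_control) + 0.5 * P(tie), which equals the trapezoidal
area under the ROC curve.  Its p-value against the chance value 0.5 uses the
null-hypothesis variance of the Mann-Whitney statistic with a normal
approximation; an exact/permutation alternative enumerates or samples label
assignments for small samples.  Operating-point predictive values follow
Bayes' rule from (sensitivity, specificity, prevalence).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ROCCurve:
    """ROC curve points from sweeping all distinct score thresholds."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class AUCResult:
    """AUC point estimate with standard error and p-value versus chance."""

    auc: float
    se: float
    p_value: float
    n_cases: int
    n_controls: int


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present; ROC/AUC undefined")
    return scores, labels


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve over all distinct thresholds, ties grouped; endpoints (0,0)/(1,1)."""
    scores, labels = _check_scores_labels(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # average ranks: half-credit for ties
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def auc(scores, labels) -> AUCResult:
    """Mann-Whitney AUC with Hanley-McNeil SE and normal-approximation p vs 0.5."""
    scores, labels = _check_scores_labels(scores, labels)
    a = _rank_auc(scores, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    # Hanley & McNeil (1982) SE of the estimate
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    result = AUCResult(auc=a, se=se, p_value=1.0, n_cases=n1, n_controls=n0)
    result.p_value = auc_pvalue(result)
    return result


def auc_pvalue(
    result: AUCResult,
    method: str = "normal",
    scores=None,
    labels=None,
    n_permutations: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for AUC != 0.5.

    ``normal`` (default) uses the null variance of the Mann-Whitney statistic,
    (n1 + n0 + 1) / (12 n1 n0), with a normal approximation.  ``exact``
    enumerates all label assignments when feasible (otherwise samples
    ``n_permutations`` of them) and needs the original scores and labels.
    """
    n1, n0 = result.n_cases, result.n_controls
    if n1 < 1 or n0 < 1:
        raise ValueError("need at least one case and one control")
    if method == "normal":
        # Mann-Whitney U scale with continuity correction: without it the
        # normal tail is far from the discrete permutation tail at small n
        u = result.auc * n1 * n0
        sigma_u = math.sqrt(n1 * n0 * (n1 + n0 + 1) / 12)
        z = max(abs(u - n1 * n0 / 2) - 0.5, 0.0) / sigma_u
        return float(min(1.0, 2 * stats.norm.sf(z)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if scores is None or labels is None:
        raise ValueError("exact method needs scores and labels")
    scores, labels = _check_scores_labels(scores, labels)
    n = len(labels)
    observed = abs(_rank_auc(scores, labels) - 0.5)
    n_total = math.comb(n, n1)
    if n_total <= n_permutations:
        hits = 0
        for case_idx in itertools.combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(case_idx)] = 1
            if abs(_rank_auc(scores, lab) - 0.5) >= observed - 1e-12:
                hits += 1
        return hits / n_total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        lab = np.zeros(n, dtype=int)
        lab[rng.choice(n, size=n1, replace=False)] = 1
        if abs(_rank_auc(scores, lab) - 0.5) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def operating_point(sensitivity: float, specificity: float, prevalence: float) -> OperatingPoint:
    """Predictive values at a threshold, via Bayes' rule.

    ppv = sens*prev / (sens*prev + (1-spec)(1-prev));
    npv = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev).
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name}={v} outside [0, 1]")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if ppv_den == 0:
        raise ZeroDivisionError(
            "PPV undefined: no predicted positives (sens*prev and (1-spec)(1-prev) both zero)"
        )
    if npv_den == 0:
        raise ZeroDivisionError(
            "NPV undefined: no predicted negatives (spec*(1-prev) and (1-sens)*prev both zero)"
        )
    return OperatingPoint(
        sensitivity=sensitivity,
        specificity=specificity,
        prevalence=prevalence,
        ppv=sensitivity * prevalence / ppv_den,
        npv=specificity * (1 - prevalence) / npv_den,
    )
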