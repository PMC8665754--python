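"""Evaluation metrics: ROC-AUC, PR-AUC and per-patient top-k recall.

ROC-AUC follows the pairwise-concordance definition (probability that a
random positive outscores a random negative, ties counted one half);
PR-AUC is the step-wise area under the precision-recall curve (precision
held constant moving right to left across recall, i.e. the average
precision over the threshold sweep). Both are delegated to scikit-learn,
which implements exactly these definitions; the test suite checks them
against brute-force oracles.

Top-k recall ranks each patient's variants by descending score and asks
what fraction of all disease-causing variants land within the top k of
their own patient — the quantity that tracks diagnostic yield.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["PatientCohort", "roc_auc", "pr_auc", "top_k_recall"]


@dataclass(frozen=True)
class PatientCohort:
    """Per-patient scored variant lists with causal flags.

    ``patients`` is a list of (scores, causal) pairs; each patient must
    carry at least one causal variant (e.g. two for recessive cases).
    """

    patients: tuple[tuple[tuple[float, ...], tuple[bool, ...]], ...]

    def __post_init__(self) -> None:
        for i, (scores, causal) in enumerate(self.patients):
            if len(scores) != len(causal):
                raise ValueError(f"patient {i}: scores and flags differ in length")
            if not any(causal):
                raise ValueError(f"patient {i} has no causal variant")

    @classmethod
    def from_lists(cls, patients) -> "PatientCohort":
        return cls(tuple(
            (tuple(float(s) for s in scores), tuple(bool(c) for c in causal))
            for scores, causal in patients
        ))


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC needs both a positive and a negative class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve; requires >=1 positive."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("PR-AUC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def top_k_recall(cohort: PatientCohort, k: int) -> float:
    """Fraction of causal variants ranked in the top k of their patient.

    Ranking is by descending score with ties broken by stable input order
    (earlier-listed variants rank first). The denominator counts every
    causal variant, so a recessive patient with two causal variants
    contributes two.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not cohort.patients:
        raise ValueError("empty cohort")
    hit = total = 0
    for scores, causal in cohort.patients:
        order = np.argsort(-np.asarray(scores), kind="stable")
        top = set(order[:k].tolist())
        for i, is_causal in enumerate(causal):
            if is_causal:
                total += 1
                if i in top:
                    hit += 1
    return hit / total
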