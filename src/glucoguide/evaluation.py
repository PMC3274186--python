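"""Match-count scoring and the three-way recommender comparison.

A prediction matches when it equals the record's true treatment label; the
score of a method on a test set is the raw match count (and the equivalent
accuracy fraction).  ``compare_methods`` evaluates the rule-based
recommender and the k-nearest-neighbor recommender — raw and min-max
normalized, for each requested k — on one shared test set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from glucoguide.knn import knn_recommend
from glucoguide.records import LabeledDataset, TreatmentCode
from glucoguide.rules import RuleSet


@dataclass(frozen=True)
class EvaluationResult:
    """Score of one method configuration on a test set."""

    method: str
    k: Optional[int]
    normalized: bool
    matches: int
    total: int
    accuracy: float
    per_record: tuple[int, ...]  # 1 = prediction equals label, else 0


def score(
    predictions: Sequence[TreatmentCode],
    labels: Sequence[TreatmentCode],
    method: str = "unnamed",
    k: Optional[int] = None,
    normalized: bool = False,
) -> EvaluationResult:
    """Elementwise match count of predictions against true labels."""
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(labels)} labels"
        )
    if not predictions:
        raise ValueError("cannot score an empty prediction sequence")
    per_record = tuple(
        int(int(p) == int(t)) for p, t in zip(predictions, labels)
    )
    matches = sum(per_record)
    total = len(per_record)
    return EvaluationResult(
        method=method,
        k=k,
        normalized=normalized,
        matches=matches,
        total=total,
        accuracy=matches / total,
        per_record=per_record,
    )


def compare_methods(
    sample: LabeledDataset,
    test: LabeledDataset,
    ks: Sequence[int] = (1, 3, 5),
    rules: Optional[RuleSet] = None,
) -> list[EvaluationResult]:
    """Score the rule-based and KNN recommenders on one test set.

    Returns one result per configuration, in a fixed order: rule-based
    first, then raw KNN for each k, then normalized KNN for each k.  The
    comparison is fully deterministic given its inputs.
    """
    if not test.fully_labeled:
        raise ValueError("test set must be fully labeled")
    rules = RuleSet.default() if rules is None else rules
    labels = [r.treatment for r in test]

    results = [
        score(
            [rules.recommend(r) for r in test],
            labels,
            method="rule_based",
        )
    ]
    for normalized in (False, True):
        for k in ks:
            predictions = [
                knn_recommend(r, sample, k=k, normalized=normalized).predicted
                for r in test
            ]
            results.append(
                score(
                    predictions,
                    labels,
                    method="knn_normalized" if normalized else "knn_raw",
                    k=k,
                    normalized=normalized,
                )
            )
    return results


def results_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Tabulate comparison results (one row per method configuration)."""
    return pd.DataFrame(
        {
            "method": [r.method for r in results],
            "k": [r.k if r.k is not None else "" for r in results],
            "normalized": [r.normalized for r in results],
            "matches": [r.matches for r in results],
            "total": [r.total for r in results],
            "accuracy": [r.accuracy for r in results],
        }
    )


def plot_comparison(results: Sequence[EvaluationResult], path: str) -> None:
    """Save a bar chart of match counts per method configuration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [
        r.method + (f" k={r.k}" if r.k is not None else "") for r in results
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(names, [r.matches for r in results], color="tab:blue")
    ax.set_ylabel(f"matches out of {results[0].total}")
    ax.set_title("Recommender comparison")
    plt.setp(ax.get_xticklabels(), rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
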