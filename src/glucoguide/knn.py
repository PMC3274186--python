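"""Min-max normalization and k-nearest-neighbor treatment recommendation.

A query record is classified by the plurality treatment label among its k
closest labeled records under Euclidean distance over the seven features.
Because the features live on very different scales (hours vs. thousands of
kcal), distances can optionally be computed after min-max scaling each
feature to [0, 1] with bounds fitted on the labeled sample set; query values
outside the fitted bounds are clamped.

Determinism: neighbors at exactly equal distance are taken in dataset
order, and a tied plurality vote is resolved in favor of the tied label
whose neighbor is nearest (so a k=3 three-way tie degenerates to the k=1
answer).  The treatment label itself is never normalized.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from glucoguide.records import (
    FEATURE_NAMES,
    LabeledDataset,
    ObservationRecord,
    TreatmentCode,
)


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(
            f"dimension mismatch: {x.shape} vs {y.shape}"
        )
    return float(np.sqrt(np.sum((x - y) ** 2)))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max bounds fitted on a sample (training) set.

    A degenerate feature (max equal to min) maps to 0 by convention and
    therefore contributes nothing to any distance.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "minimum", np.asarray(self.minimum, dtype=float)
        )
        object.__setattr__(
            self, "maximum", np.asarray(self.maximum, dtype=float)
        )
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("minimum and maximum must have the same shape")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum for every feature")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of features with max == min."""
        return self.maximum == self.minimum

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Scale features to [0, 1]: (value - min) / (max - min), clamped."""
        features = np.asarray(features, dtype=float)
        span = np.where(self.degenerate, 1.0, self.maximum - self.minimum)
        scaled = (features - self.minimum) / span
        scaled = np.where(self.degenerate, 0.0, scaled)
        return np.clip(scaled, 0.0, 1.0)

    # small JSON document so fitted bounds can be audited or reused
    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "features": list(FEATURE_NAMES),
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            minimum=np.array(payload["minimum"], dtype=float),
            maximum=np.array(payload["maximum"], dtype=float),
        )

    @classmethod
    def from_ranges(
        cls, ranges: dict[str, tuple[float, float]]
    ) -> "NormalizationParams":
        """Build params from a {feature: (min, max)} mapping."""
        missing = [n for n in FEATURE_NAMES if n not in ranges]
        if missing:
            raise ValueError(f"missing range(s) for: {', '.join(missing)}")
        return cls(
            minimum=np.array([ranges[n][0] for n in FEATURE_NAMES], float),
            maximum=np.array([ranges[n][1] for n in FEATURE_NAMES], float),
        )


def fit_normalization(sample: LabeledDataset) -> NormalizationParams:
    """Per-feature min/max over the sample records."""
    if len(sample) == 0:
        raise ValueError("cannot fit normalization on an empty dataset")
    matrix = sample.feature_matrix()
    return NormalizationParams(
        minimum=matrix.min(axis=0), maximum=matrix.max(axis=0)
    )


def normalize(
    record: ObservationRecord, params: NormalizationParams
) -> ObservationRecord:
    """Min-max scale a record's seven features; the treatment label is copied."""
    return record.with_features(params.transform(record.features()))


@dataclass(frozen=True)
class VoteResult:
    """Outcome of one k-nearest-neighbor vote.

    ``neighbor_indices`` index into the sample dataset, ordered by
    non-decreasing distance; ``tally`` counts votes per candidate code and
    sums to k.
    """

    predicted: TreatmentCode
    neighbor_indices: tuple[int, ...]
    neighbor_distances: tuple[float, ...]
    tally: dict[TreatmentCode, int]


def knn_recommend(
    query: ObservationRecord,
    sample: LabeledDataset,
    k: int = 3,
    normalized: bool = False,
) -> VoteResult:
    """Classify a query record by plurality vote of its k nearest neighbors.

    Parameters
    ----------
    query
        The record to classify; its treatment label, if any, is ignored.
    sample
        Fully labeled memory set; must contain at least ``k`` records.
    k
        Number of neighbors (1, 3 and 5 are the intended settings; any
        positive k up to the sample size works).
    normalized
        If True, min-max bounds are fitted on ``sample`` and applied to
        both the sample and the query (with clamping) before computing
        distances.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(sample):
        raise ValueError(f"k={k} exceeds sample size {len(sample)}")
    labels = sample.labels()  # raises if any record is unlabeled

    matrix = sample.feature_matrix()
    query_vec = query.features()
    if normalized:
        params = fit_normalization(sample)
        matrix = params.transform(matrix)
        query_vec = params.transform(query_vec)

    distances = np.sqrt(np.sum((matrix - query_vec) ** 2, axis=1))
    order = np.argsort(distances, kind="stable")  # equal distances: dataset order
    nearest = order[:k]

    tally = Counter(TreatmentCode(int(labels[i])) for i in nearest)
    best_count = max(tally.values())
    tied = {code for code, count in tally.items() if count == best_count}
    if len(tied) == 1:
        predicted = tied.pop()
    else:
        # tie-break: the tied label whose representative is nearest
        predicted = next(
            TreatmentCode(int(labels[i]))
            for i in nearest
            if TreatmentCode(int(labels[i])) in tied
        )

    return VoteResult(
        predicted=predicted,
        neighbor_indices=tuple(int(i) for i in nearest),
        neighbor_distances=tuple(float(distances[i]) for i in nearest),
        tally=dict(tally),
    )
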