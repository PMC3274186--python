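"""Shared fixtures and the independent brute-force nearest-neighbor oracle."""

from __future__ import annotations

import math
from collections import Counter

import pytest

from glucoguide import (
    LabeledDataset,
    ObservationRecord,
    RuleSet,
    load_table4,
    load_table6,
)
from glucoguide.records import FEATURE_NAMES


@pytest.fixture(scope="session")
def table4() -> LabeledDataset:
    return load_table4()


@pytest.fixture(scope="session")
def table6() -> LabeledDataset:
    return load_table6()


@pytest.fixture(scope="session")
def default_rules() -> RuleSet:
    return RuleSet.default()


def brute_force_knn(
    query: ObservationRecord,
    sample: LabeledDataset,
    k: int,
    normalized: bool = False,
    squared: bool = False,
) -> int:
    """Exhaustive-search nearest-neighbor vote, written independently.

    Pure-Python loops: compute every distance, sort by (distance, index),
    take the first k, count votes, break count ties in favor of the tied
    label appearing earliest in the distance-sorted neighbor list.  With
    ``squared`` the square root is skipped, which must not change the
    answer (monotone transform of the distance).
    """
    if normalized:
        # explicit scans, one feature at a time
        bounds = {}
        for name in FEATURE_NAMES:
            values = [getattr(r, name) for r in sample]
            bounds[name] = (min(values), max(values))

        def coords(record):
            out = []
            for name in FEATURE_NAMES:
                low, high = bounds[name]
                if high == low:
                    out.append(0.0)
                else:
                    out.append(min(1.0, max(0.0, (getattr(record, name) - low) / (high - low))))
            return out

    else:

        def coords(record):
            return [getattr(record, name) for name in FEATURE_NAMES]

    query_coords = coords(query)
    scored = []
    for index, record in enumerate(sample):
        total = sum((a - b) ** 2 for a, b in zip(coords(record), query_coords))
        distance = total if squared else math.sqrt(total)
        scored.append((distance, index, int(record.treatment)))
    scored.sort(key=lambda item: (item[0], item[1]))
    nearest = scored[:k]
    counts = Counter(label for _, _, label in nearest)
    best = max(counts.values())
    for _, _, label in nearest:
        if counts[label] == best:
            return label
    raise AssertionError("unreachable")
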