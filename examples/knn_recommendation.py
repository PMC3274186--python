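"""Nearest-neighbor treatment advice from labeled example records.

The packaged 10-row sample table serves as KNN memory.  A query record is
classified by the plurality treatment label among its k nearest rows under
Euclidean distance over the seven features, optionally after min-max
scaling each feature to [0, 1] with bounds fitted on the sample.
"""

from glucoguide import ObservationRecord, knn_recommend, load_table4

sample = load_table4()
query = ObservationRecord(
    time=10, blood_sugar=90, systolic=150, diastolic=72,
    exercise=0, meal=0, target_calories=1600,
)

for normalized in (False, True):
    vote = knn_recommend(query, sample, k=3, normalized=normalized)
    mode = "normalized" if normalized else "raw"
    print(f"[{mode}] predicted treatment {int(vote.predicted)}: "
          f"{vote.predicted.description}")
    print(f"  neighbors (index, distance): "
          + ", ".join(f"({i}, {d:.3f})"
                      for i, d in zip(vote.neighbor_indices,
                                      vote.neighbor_distances)))
    print(f"  vote tally: { {int(c): n for c, n in vote.tally.items()} }")

print()
print("Raw distances are dominated by the large-scale calorie features; "
      "min-max scaling lets every feature influence the neighbor choice.")
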