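"""Domain types for patients and glucose observations, plus CSV I/O.

An observation record carries seven numeric features — hour of day, blood
sugar (mg/dL), systolic and diastolic blood pressure (mmHg), calories burned
by exercise, calories eaten at a meal, and the daily target calorie intake —
plus an optional treatment label.  Record files are plain CSV with a header;
thousands separators ("1,267") are accepted on read but never written.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Column order of the seven numeric features, everywhere in the package.
FEATURE_NAMES: tuple[str, ...] = (
    "time",
    "blood_sugar",
    "systolic",
    "diastolic",
    "exercise",
    "meal",
    "target_calories",
)

TREATMENT_COLUMN = "treatment"


class TreatmentCode(enum.IntEnum):
    """The five-way treatment action code.

    1 = more exercise, 2 = eat more (meal or snack), 3 = emergency (rest),
    4 = take insulin, 5 = normal (maintenance).
    """

    MORE_EXERCISE = 1
    EAT_MORE = 2
    REST = 3
    TAKE_INSULIN = 4
    MAINTAIN = 5

    @property
    def description(self) -> str:
        return _TREATMENT_DESCRIPTIONS[self]


_TREATMENT_DESCRIPTIONS = {
    TreatmentCode.MORE_EXERCISE: "more exercise",
    TreatmentCode.EAT_MORE: "eat more such as a meal or snack",
    TreatmentCode.REST: "emergency (rest)",
    TreatmentCode.TAKE_INSULIN: "take insulin",
    TreatmentCode.MAINTAIN: "normal (maintenance)",
}

ACTIVITY_CLASSES = ("light", "normal", "hard")
SEXES = ("female", "male")


class RecordParseError(ValueError):
    """Raised when a record file or cell cannot be parsed or is out of range."""


@dataclass(frozen=True)
class PatientProfile:
    """Static body information used for the daily calorie target.

    Height is in meters, weight in kilograms; ``activity`` is one of the
    three activity classes (light / normal / hard) that select the
    kcal-per-kg band.
    """

    name: str
    age: int
    sex: str
    height: float
    weight: float
    activity: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0.5 < self.height < 2.5:
            raise ValueError(
                f"height must lie in (0.5, 2.5) m, got {self.height}"
            )
        if not 20 < self.weight < 300:
            raise ValueError(
                f"weight must lie in (20, 300) kg, got {self.weight}"
            )
        if self.activity not in ACTIVITY_CLASSES:
            raise ValueError(
                f"activity must be one of {ACTIVITY_CLASSES}, got {self.activity!r}"
            )


@dataclass(frozen=True)
class ObservationRecord:
    """One timestamped measurement with an optional treatment label.

    All seven features must be finite and non-negative; ``time`` is an hour
    of day in [0, 24] (real-valued — fractional hours are allowed even
    though printed data uses whole hours).
    """

    time: float
    blood_sugar: float
    systolic: float
    diastolic: float
    exercise: float
    meal: float
    target_calories: float
    treatment: Optional[TreatmentCode] = None

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"{name} must be finite and >= 0, got {value}"
                )
        if not 0 <= self.time <= 24:
            raise ValueError(f"time must lie in [0, 24], got {self.time}")
        if self.treatment is not None:
            object.__setattr__(
                self, "treatment", TreatmentCode(int(self.treatment))
            )

    def validate_raw(self) -> None:
        """Check invariants that hold only for raw (unnormalized) records."""
        if not self.systolic > self.diastolic:
            raise ValueError(
                "systolic must exceed diastolic in a raw record, got "
                f"{self.systolic} <= {self.diastolic}"
            )

    def features(self) -> np.ndarray:
        """The seven features as a float vector in :data:`FEATURE_NAMES` order."""
        return np.array(
            [getattr(self, name) for name in FEATURE_NAMES], dtype=float
        )

    def with_features(self, values: Sequence[float]) -> "ObservationRecord":
        """A copy with the seven features replaced, treatment unchanged."""
        if len(values) != len(FEATURE_NAMES):
            raise ValueError("expected exactly 7 feature values")
        return replace(self, **dict(zip(FEATURE_NAMES, map(float, values))))


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered, index-addressable collection of observation records.

    Order is significant: it provides the deterministic tie-break for
    nearest-neighbor selection at equal distance.
    """

    records: tuple[ObservationRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ObservationRecord]:
        return iter(self.records)

    def __getitem__(self, index: int) -> ObservationRecord:
        return self.records[index]

    @property
    def fully_labeled(self) -> bool:
        return all(r.treatment is not None for r in self.records)

    def feature_matrix(self) -> np.ndarray:
        """An (n, 7) float matrix of the features, in record order."""
        if not self.records:
            return np.empty((0, len(FEATURE_NAMES)))
        return np.vstack([r.features() for r in self.records])

    def labels(self) -> np.ndarray:
        """Treatment labels as an int vector; error if any record is unlabeled."""
        if not self.fully_labeled:
            raise ValueError("dataset contains unlabeled records")
        return np.array([int(r.treatment) for r in self.records])

    def hold_out(self, index: int) -> tuple[ObservationRecord, "LabeledDataset"]:
        """Split off one record, returning (record, remaining dataset)."""
        rest = self.records[:index] + self.records[index + 1 :]
        return self.records[index], LabeledDataset(rest)


def _parse_cell(raw: object, row: int, column: str) -> float:
    if isinstance(raw, str):
        raw = raw.replace(",", "").strip()
    try:
        value = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise RecordParseError(
            f"row {row}, column {column!r}: non-numeric value {raw!r}"
        ) from None
    return value


def read_records(
    path: Union[str, Path],
    labeled: Optional[bool] = None,
    normalized: bool = False,
) -> LabeledDataset:
    """Read a CSV record file into a :class:`LabeledDataset`.

    Parameters
    ----------
    path
        CSV file with header columns
        ``time,blood_sugar,systolic,diastolic,exercise,meal,target_calories``
        and optionally ``treatment``.  Thousands separators inside quoted
        numeric cells are accepted.
    labeled
        If True, require the treatment column to be present and filled; if
        False, ignore any treatment column; if None (default), read labels
        when the column exists.
    normalized
        If True, skip the raw-record check ``systolic > diastolic`` (it does
        not hold for min-max scaled data).

    Raises
    ------
    RecordParseError
        On a missing column, a non-numeric cell or an out-of-range value,
        naming the offending row and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise RecordParseError(f"missing column(s): {', '.join(missing)}")
    has_treatment = TREATMENT_COLUMN in frame.columns
    if labeled is True and not has_treatment:
        raise RecordParseError(f"missing column(s): {TREATMENT_COLUMN}")
    use_labels = has_treatment and labeled is not False

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        values = {
            name: _parse_cell(getattr(row, name), i, name)
            for name in FEATURE_NAMES
        }
        treatment: Optional[TreatmentCode] = None
        if use_labels:
            raw = getattr(row, TREATMENT_COLUMN)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
                isinstance(raw, str) and not raw.strip()
            ):
                if labeled is True:
                    raise RecordParseError(
                        f"row {i}, column {TREATMENT_COLUMN!r}: missing label"
                    )
            else:
                code = _parse_cell(raw, i, TREATMENT_COLUMN)
                if code != int(code) or not 1 <= code <= 5:
                    raise RecordParseError(
                        f"row {i}, column {TREATMENT_COLUMN!r}: "
                        f"treatment must be an integer 1-5, got {raw!r}"
                    )
                treatment = TreatmentCode(int(code))
        try:
            record = ObservationRecord(treatment=treatment, **values)
            if not normalized:
                record.validate_raw()
        except ValueError as exc:
            raise RecordParseError(f"row {i}: {exc}") from None
        records.append(record)
    return LabeledDataset(tuple(records))


def write_records(dataset: LabeledDataset, path: Union[str, Path]) -> None:
    """Write a dataset to CSV, re-readable by :func:`read_records`.

    Numeric fields are rendered without thousands separators.  The treatment
    column is written whenever at least one record carries a label; missing
    labels are left blank.
    """
    path = Path(path)
    any_labeled = any(r.treatment is not None for r in dataset)
    columns: dict[str, list] = {
        name: [getattr(r, name) for r in dataset] for name in FEATURE_NAMES
    }
    frame = pd.DataFrame(columns, columns=list(FEATURE_NAMES))
    if any_labeled:
        frame[TREATMENT_COLUMN] = pd.array(
            [None if r.treatment is None else int(r.treatment) for r in dataset],
            dtype="Int64",
        )
    frame.to_csv(path, index=False)


def _load_fixture(name: str, normalized: bool) -> LabeledDataset:
    source = resources.files("glucoguide.data").joinpath(name)
    with resources.as_file(source) as fixture:
        return read_records(fixture, labeled=True, normalized=normalized)


def load_table4() -> LabeledDataset:
    """The packaged 10-row raw sample/test table (labeled)."""
    return _load_fixture("table4.csv", normalized=False)


def load_table6() -> LabeledDataset:
    """The packaged min-max-normalized twin of the 10-row table."""
    return _load_fixture("table6.csv", normalized=True)
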