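"""Domain types and I/O for long-format stability tables.

A stability table holds one normalized potency measurement per
(batch, molecular type, container, temperature, time) coordinate, stored as
CSV with the fixed header::

    batch_id,molecular_type,container,temperature_C,time_months,potency

One dialect only: comma separated, period decimal, UTF-8.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Container",
    "StabilityRecord",
    "StabilityDataset",
    "SchemaError",
    "RecordValidationError",
    "CSV_COLUMNS",
    "read_stability_table",
    "write_stability_table",
    "split_by_time",
]

CSV_COLUMNS = (
    "batch_id",
    "molecular_type",
    "container",
    "temperature_C",
    "time_months",
    "potency",
)


class Container(str, enum.Enum):
    """Package/container presentation; vial is the modelling reference level."""

    VIAL = "vial"
    SYRINGE = "syringe"


class SchemaError(ValueError):
    """Raised when a CSV file does not match the documented column contract."""


class RecordValidationError(ValueError):
    """Raised when one or more rows violate the record invariants.

    Carries ``rows``: a list of (row_index, message) pairs, with row_index
    counted over data rows (0-based, header excluded).
    """

    def __init__(self, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"row {i}: {msg}" for i, msg in rows[:10])
        extra = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
        super().__init__(f"invalid stability records: {detail}{extra}")


@dataclass(frozen=True)
class StabilityRecord:
    """One potency measurement at a (batch, type, container, T, t) coordinate."""

    batch_id: str
    molecular_type: str
    container: Container
    temperature_C: float
    time_months: float
    potency: float

    def validate(self) -> list[str]:
        problems = []
        if not (math.isfinite(self.time_months) and self.time_months >= 0):
            problems.append(f"time_months must be finite and >= 0, got {self.time_months}")
        if not (math.isfinite(self.potency) and self.potency > 0):
            problems.append(f"potency must be finite and > 0, got {self.potency}")
        if not isinstance(self.container, Container):
            problems.append(f"unknown container {self.container!r}")
        return problems


@dataclass
class StabilityDataset:
    """Ordered collection of :class:`StabilityRecord` with study-level metadata.

    Invariants enforced on construction:

    * every record passes its own validation;
    * each temperature is a member of the declared temperature set;
    * every batch maps to exactly one container;
    * every batch carries the same set of molecular types (only checked when
      more than one batch is present and ``check_balanced`` is left on);
    * duplicate coordinates are permitted and flagged as replicates.
    """

    records: list[StabilityRecord]
    type_labels: tuple[str, ...] = ()
    temperature_set: tuple[float, ...] = ()
    spec_limit: float | None = None
    check_balanced: bool = True
    has_replicates: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not self.type_labels:
            seen: dict[str, None] = {}
            for r in self.records:
                seen.setdefault(r.molecular_type, None)
            self.type_labels = tuple(seen)
        if not self.temperature_set:
            temps: dict[float, None] = {}
            for r in self.records:
                temps.setdefault(r.temperature_C, None)
            self.temperature_set = tuple(temps)
        self._validate()

    def _validate(self) -> None:
        problems: list[tuple[int, str]] = []
        batch_container: dict[str, Container] = {}
        keys: set[tuple] = set()
        replicates = False
        tset = set(self.temperature_set)
        for i, r in enumerate(self.records):
            problems.extend((i, p) for p in r.validate())
            if r.temperature_C not in tset:
                problems.append(
                    (i, f"temperature {r.temperature_C} not in declared set {sorted(tset)}")
                )
            prev = batch_container.setdefault(r.batch_id, r.container)
            if prev is not r.container:
                problems.append(
                    (i, f"batch {r.batch_id} maps to both {prev.value} and {r.container.value}")
                )
            key = (r.batch_id, r.molecular_type, r.container, r.temperature_C, r.time_months)
            if key in keys:
                replicates = True
            keys.add(key)
        if self.check_balanced and len(batch_container) > 1:
            per_batch: dict[str, set[str]] = {}
            for r in self.records:
                per_batch.setdefault(r.batch_id, set()).add(r.molecular_type)
            ref = next(iter(per_batch.values()))
            for b, types in per_batch.items():
                if types != ref:
                    problems.append((-1, f"batch {b} carries a different molecular-type set"))
                    break
        if problems:
            raise RecordValidationError(problems)
        self.has_replicates = replicates

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[StabilityRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view with the CSV column contract."""
        return pd.DataFrame(
            {
                "batch_id": [r.batch_id for r in self.records],
                "molecular_type": [r.molecular_type for r in self.records],
                "container": [r.container.value for r in self.records],
                "temperature_C": np.array([r.temperature_C for r in self.records], float),
                "time_months": np.array([r.time_months for r in self.records], float),
                "potency": np.array([r.potency for r in self.records], float),
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        type_labels: Sequence[str] = (),
        temperature_set: Sequence[float] = (),
        spec_limit: float | None = None,
        check_balanced: bool = True,
    ) -> "StabilityDataset":
        records = [
            StabilityRecord(
                batch_id=str(row.batch_id),
                molecular_type=str(row.molecular_type),
                container=Container(row.container),
                temperature_C=float(row.temperature_C),
                time_months=float(row.time_months),
                potency=float(row.potency),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(
            records,
            type_labels=tuple(type_labels),
            temperature_set=tuple(float(t) for t in temperature_set),
            spec_limit=spec_limit,
            check_balanced=check_balanced,
        )

    def batch_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.batch_id, None)
        return tuple(seen)

    def container_of(self, batch_id: str) -> Container:
        for r in self.records:
            if r.batch_id == batch_id:
                return r.container
        raise KeyError(batch_id)

    def subset(self, mask: Sequence[bool]) -> "StabilityDataset":
        records = [r for r, keep in zip(self.records, mask) if keep]
        return StabilityDataset(
            records,
            type_labels=self.type_labels,
            temperature_set=self.temperature_set,
            spec_limit=self.spec_limit,
            check_balanced=False,
        )


def read_stability_table(path: str | Path, spec_limit: float | None = None) -> StabilityDataset:
    """Read a stability CSV, validating schema and record invariants.

    Raises :class:`SchemaError` for missing/renamed columns and
    :class:`RecordValidationError` with row-numbered diagnostics for
    non-numeric or invariant-violating values.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; expected header {list(CSV_COLUMNS)}")

    problems: list[tuple[int, str]] = []
    numeric: dict[str, np.ndarray] = {}
    for col in ("temperature_C", "time_months", "potency"):
        values = pd.to_numeric(raw[col], errors="coerce")
        for i in np.flatnonzero(values.isna().to_numpy()):
            problems.append((int(i), f"non-numeric {col} {raw[col].iloc[i]!r}"))
        numeric[col] = values.to_numpy(float)

    containers: list[Container | None] = []
    valid_tokens = {c.value for c in Container}
    for i, token in enumerate(raw["container"]):
        if token not in valid_tokens:
            problems.append((int(i), f"unknown container token {token!r}"))
            containers.append(None)
        else:
            containers.append(Container(token))
    if problems:
        raise RecordValidationError(problems)

    records = [
        StabilityRecord(
            batch_id=str(raw["batch_id"].iloc[i]),
            molecular_type=str(raw["molecular_type"].iloc[i]),
            container=containers[i],  # type: ignore[arg-type]
            temperature_C=float(numeric["temperature_C"][i]),
            time_months=float(numeric["time_months"][i]),
            potency=float(numeric["potency"][i]),
        )
        for i in range(len(raw))
    ]
    return StabilityDataset(records, spec_limit=spec_limit)


def write_stability_table(ds: StabilityDataset, path: str | Path) -> Path:
    """Write ``ds`` as CSV under the documented column contract.

    ``read_stability_table(write_stability_table(ds, p))`` reproduces ``ds``.
    """
    path = Path(path)
    frame = ds.to_frame() if ds.records else pd.DataFrame(columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def split_by_time(
    ds: StabilityDataset,
    cutoff_months: float,
    holdout_temperature: float | None = None,
) -> tuple[StabilityDataset, StabilityDataset]:
    """Time-split: train = records with time <= cutoff (all temperatures),
    test = records with time > cutoff, optionally restricted to one
    temperature. Raises ``ValueError`` when the training split is empty.
    """
    if cutoff_months < 0:
        raise ValueError(f"cutoff_months must be >= 0, got {cutoff_months}")
    train_mask = [r.time_months <= cutoff_months for r in ds.records]
    if not any(train_mask):
        raise ValueError(f"cutoff {cutoff_months} months excludes all training data")
    test_mask = [
        (r.time_months > cutoff_months)
        and (holdout_temperature is None or r.temperature_C == holdout_temperature)
        for r in ds.records
    ]
    return ds.subset(train_mask), ds.subset(test_mask)
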