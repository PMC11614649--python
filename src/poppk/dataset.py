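"""NONMEM-style longitudinal event tables.

One row per event: a dose (EVID=1, with AMT) or an observation (EVID=0,
with DV).  Subject-level covariates (weight and binary comedication
flags, plus arbitrary extra numeric columns) are repeated on every row.
Times are decimal hours with 0 at each subject's first dose.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EventRecord",
    "TDMDataset",
    "ValidationIssue",
    "DatasetError",
    "DatasetFormatError",
    "DatasetParseError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "DEFAULT_DIALECT",
]


class DatasetError(ValueError):
    """Base class for event-table problems."""


class DatasetFormatError(DatasetError):
    """A required column is missing or the file is not a usable CSV."""


class DatasetParseError(DatasetError):
    """A cell could not be parsed; message carries the row index."""


class DatasetValidationError(DatasetError):
    """Dataset-level invariants are violated."""

    def __init__(self, issues: Sequence["ValidationIssue"]):
        self.issues = list(issues)
        msg = "; ".join(f"{i.subject_id}: {i.reason}" for i in self.issues)
        super().__init__(f"invalid dataset: {msg}")


#: Default NONMEM-flavoured column names.  Keys are internal field roles,
#: values are CSV headers; pass a partial override as ``dialect``.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "ID",
    "time": "TIME",
    "amt": "AMT",
    "dv": "DV",
    "evid": "EVID",
    "wt": "WT",
    "flu": "FLU",
    "dul": "DUL",
}

_OPTIONAL_MDV = "MDV"


@dataclass(frozen=True)
class EventRecord:
    """A single dose or observation event.

    Exactly one of ``amount`` (dose rows) and ``concentration``
    (observation rows) is set.  ``weight`` is kg, ``concentration``
    ng/mL, ``amount`` mg.  ``extras`` holds additional numeric
    subject-level covariates keyed by column name.
    """

    subject_id: str
    time: float
    is_dose: bool
    amount: float | None = None
    concentration: float | None = None
    weight: float = 70.0
    flu: float = 0.0
    dul: float = 0.0
    extras: Mapping[str, float] = field(default_factory=dict)

    def covariates(self) -> dict[str, float]:
        """Covariate values keyed by canonical column name."""
        out = {"WT": self.weight, "FLU": self.flu, "DUL": self.dul}
        out.update(self.extras)
        return out


@dataclass(frozen=True)
class ValidationIssue:
    subject_id: str
    reason: str


class TDMDataset:
    """Event records grouped by subject and time-sorted within subject.

    Subject order follows first appearance in the input; within a
    subject, records are ordered by time with doses before observations
    at equal times (a sample drawn at a dosing time is a pre-dose
    trough).
    """

    def __init__(self, records: Iterable[EventRecord]):
        groups: dict[str, list[EventRecord]] = {}
        for r in records:
            groups.setdefault(str(r.subject_id), []).append(r)
        ordered: list[EventRecord] = []
        for sid, recs in groups.items():
            recs.sort(key=lambda r: (r.time, 0 if r.is_dose else 1))
            ordered.extend(recs)
        self._records: tuple[EventRecord, ...] = tuple(ordered)
        self._subjects: tuple[str, ...] = tuple(groups)

    @property
    def records(self) -> tuple[EventRecord, ...]:
        return self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def n_subjects(self) -> int:
        return len(self._subjects)

    @property
    def n_observations(self) -> int:
        return sum(1 for r in self._records if not r.is_dose)

    @property
    def n_doses(self) -> int:
        return sum(1 for r in self._records if r.is_dose)

    def subjects(self) -> tuple[str, ...]:
        return self._subjects

    def subject_records(self, subject_id: str) -> list[EventRecord]:
        sid = str(subject_id)
        recs = [r for r in self._records if r.subject_id == sid]
        if not recs:
            raise KeyError(f"unknown subject {subject_id!r}")
        return recs

    def extra_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for r in self._records:
            for k in r.extras:
                if k not in names:
                    names.append(k)
        return tuple(names)

    def subject_covariates(self) -> pd.DataFrame:
        """One row per subject with WT, FLU, DUL and any extra covariates."""
        rows = []
        for sid in self._subjects:
            rows.append(self.subject_records(sid)[0].covariates())
        return pd.DataFrame(rows, index=list(self._subjects))

    def subset(self, subject_ids: Sequence[str]) -> "TDMDataset":
        recs: list[EventRecord] = []
        for sid in subject_ids:
            recs.extend(self.subject_records(sid))
        return TDMDataset(recs)

    def equals(self, other: "TDMDataset", rtol: float = 1e-10) -> bool:
        """Field-level equality with relative tolerance on numeric fields."""
        if len(self) != len(other):
            return False

        def close(a: float | None, b: float | None) -> bool:
            if a is None or b is None:
                return a is None and b is None
            if a == b:
                return True
            return abs(a - b) <= rtol * max(abs(a), abs(b))

        for ra, rb in zip(self._records, other._records):
            if ra.subject_id != rb.subject_id or ra.is_dose != rb.is_dose:
                return False
            if not (close(ra.time, rb.time) and close(ra.amount, rb.amount)
                    and close(ra.concentration, rb.concentration)
                    and close(ra.weight, rb.weight)
                    and close(ra.flu, rb.flu) and close(ra.dul, rb.dul)):
                return False
            if set(ra.extras) != set(rb.extras):
                return False
            if not all(close(ra.extras[k], rb.extras[k]) for k in ra.extras):
                return False
        return True


def _parse_cell(value: str, row: int, column: str, *, required: bool) -> float | None:
    text = value.strip()
    if text == "" or text == ".":
        if required:
            raise DatasetParseError(
                f"row {row}: missing value in required column {column!r}")
        return None
    try:
        return float(text)
    except ValueError:
        raise DatasetParseError(
            f"row {row}: non-numeric value {value!r} in column {column!r}") from None


def read_dataset(path, dialect: Mapping[str, str] | None = None) -> TDMDataset:
    """Read and validate a NONMEM-style event CSV.

    Parameters
    ----------
    path:
        CSV file with a header row.
    dialect:
        Optional partial override of :data:`DEFAULT_DIALECT`, mapping
        internal roles (``id``, ``time``, ``amt``, ``dv``, ``evid``,
        ``wt``, ``flu``, ``dul``) to the file's column names.

    Raises
    ------
    DatasetFormatError
        If a required column is absent (the message names it).
    DatasetParseError
        On a non-numeric cell (the message carries the row index).
    DatasetValidationError
        If the parsed dataset violates an invariant, e.g. an
        observation precedes its subject's first dose.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - malformed CSV edge
        raise DatasetFormatError(f"could not read {path}: {exc}") from exc

    for role in ("id", "time", "amt", "dv", "evid", "wt", "flu", "dul"):
        if cols[role] not in frame.columns:
            raise DatasetFormatError(f"missing required column {cols[role]!r}")

    known = set(cols.values()) | {_OPTIONAL_MDV}
    extra_cols = [c for c in frame.columns if c not in known]
    has_mdv = _OPTIONAL_MDV in frame.columns

    records: list[EventRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        evid = _parse_cell(row[cols["evid"]], i, cols["evid"], required=True)
        if evid not in (0.0, 1.0):
            raise DatasetParseError(f"row {i}: unsupported EVID {evid!r}")
        is_dose = evid == 1.0
        if not is_dose and has_mdv:
            mdv = _parse_cell(row[_OPTIONAL_MDV], i, _OPTIONAL_MDV, required=False)
            if mdv == 1.0:
                continue  # missing DV observation row
        time = _parse_cell(row[cols["time"]], i, cols["time"], required=True)
        amount = _parse_cell(row[cols["amt"]], i, cols["amt"], required=is_dose)
        conc = _parse_cell(row[cols["dv"]], i, cols["dv"], required=not is_dose)
        extras = {c: _parse_cell(row[c], i, c, required=True) for c in extra_cols}
        records.append(EventRecord(
            subject_id=str(row[cols["id"]]).strip(),
            time=float(time),
            is_dose=is_dose,
            amount=amount if is_dose else None,
            concentration=None if is_dose else conc,
            weight=_parse_cell(row[cols["wt"]], i, cols["wt"], required=True),
            flu=_parse_cell(row[cols["flu"]], i, cols["flu"], required=True),
            dul=_parse_cell(row[cols["dul"]], i, cols["dul"], required=True),
            extras=extras,
        ))

    ds = TDMDataset(records)
    issues = validate_dataset(ds)
    if issues:
        raise DatasetValidationError(issues)
    return ds


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return "%.12g" % float(value)


def write_dataset(ds: TDMDataset, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a dataset as CSV readable by :func:`read_dataset`.

    Numeric fields are rendered with 12 significant digits so a
    read/write round trip preserves values to at least 10 significant
    digits, and write->read->write is byte-idempotent.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    extra_names = list(ds.extra_names())
    header = [cols["id"], cols["time"], cols["evid"], cols["amt"], cols["dv"],
              cols["wt"], cols["flu"], cols["dul"], *extra_names]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for r in ds:
            writer.writerow([
                r.subject_id,
                _fmt(r.time),
                "1" if r.is_dose else "0",
                _fmt(r.amount),
                _fmt(r.concentration),
                _fmt(r.weight),
                _fmt(r.flu),
                _fmt(r.dul),
                *[_fmt(r.extras.get(name)) for name in extra_names],
            ])


def validate_dataset(ds: TDMDataset) -> list[ValidationIssue]:
    """Check all dataset invariants; return issues instead of raising.

    An empty list means the dataset is valid.
    """
    issues: list[ValidationIssue] = []
    for sid in ds.subjects():
        recs = ds.subject_records(sid)
        first_cov = recs[0].covariates()
        dose_times = [r.time for r in recs if r.is_dose]
        obs_times = [r.time for r in recs if not r.is_dose]
        if not dose_times:
            issues.append(ValidationIssue(sid, "subject has no dose record"))
        elif obs_times and min(obs_times) < min(dose_times):
            issues.append(ValidationIssue(sid, "observation before first dose"))
        for r in recs:
            if r.is_dose and (r.amount is None or r.concentration is not None):
                issues.append(ValidationIssue(sid, "dose record must carry amount only"))
            if not r.is_dose and (r.concentration is None or r.amount is not None):
                issues.append(ValidationIssue(
                    sid, "observation record must carry concentration only"))
            if not (r.time >= 0.0):
                issues.append(ValidationIssue(sid, f"negative time {r.time}"))
            if not (r.weight > 0.0):
                issues.append(ValidationIssue(sid, f"non-positive weight {r.weight}"))
            if r.flu not in (0.0, 1.0) or r.dul not in (0.0, 1.0):
                issues.append(ValidationIssue(sid, "flag not in {0,1}"))
            if r.covariates() != first_cov:
                issues.append(ValidationIssue(sid, "covariates vary within subject"))
    return issues
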