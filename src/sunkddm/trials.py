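"""Trial-log data model and CSV session I/O.

A *trial* is one encounter with a reward site on a delay-foraging task
(Restaurant-Row style for rodents, Web-Surf style for humans): the subject is
shown an offer delay, accepts or skips it, and — if it accepted — either waits
out the countdown and earns the reward or quits partway through.  Every data
source in this package (the drift-diffusion simulator, the hazard-model
synthetic generator, or a real session exported to this schema) speaks this
one format, so every measure downstream can assume a validated table.

The on-disk format is a plain UTF-8 CSV with a header row and the columns::

    subject_id, session_id, site_id, offer_s, accepted, time_spent_s, outcome, w0

``accepted`` is 0/1, ``outcome`` is one of ``skip``/``quit``/``earn``, and
``w0`` (the simulator's initial willingness-to-wait) is blank when unknown.
Session-level provenance (generator name, config hash, seed) is written to a
JSON sidecar next to the CSV (``<name>.meta.json``).
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "CSV_COLUMNS",
    "TrialRecord",
    "SessionSet",
    "Violation",
    "SchemaError",
    "TrialValidationError",
    "validate_trials",
    "read_trials_csv",
    "write_trials_csv",
]

OUTCOMES = ("skip", "quit", "earn")

CSV_COLUMNS = [
    "subject_id",
    "session_id",
    "site_id",
    "offer_s",
    "accepted",
    "time_spent_s",
    "outcome",
    "w0",
]


class SchemaError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class TrialValidationError(ValueError):
    """A row violates the trial invariants; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


@dataclass(frozen=True)
class Violation:
    """One invariant violation, as data rather than an exception."""

    row: int
    message: str


@dataclass(frozen=True)
class TrialRecord:
    """One offer encounter.

    Invariants (enforced by :func:`validate_trials`):

    * ``outcome == "skip"`` iff ``accepted`` is False, and then
      ``time_spent_s == 0``;
    * ``outcome == "earn"`` implies ``time_spent_s == offer_s``;
    * ``outcome == "quit"`` implies ``1 <= time_spent_s <= offer_s - 1``
      (quit checks never fire at the reward instant).
    """

    subject_id: str
    session_id: str
    site_id: str
    offer_s: int
    accepted: bool
    time_spent_s: int
    outcome: str
    w0: float | None = None


def _record_violations(rec: TrialRecord, row: int, offer_support: tuple[int, int]) -> list[Violation]:
    out: list[Violation] = []
    lo, hi = offer_support
    if rec.outcome not in OUTCOMES:
        out.append(Violation(row, f"unknown outcome {rec.outcome!r}"))
        return out
    if not (lo <= rec.offer_s <= hi):
        out.append(Violation(row, f"offer_s={rec.offer_s} outside support [{lo},{hi}]"))
    if (rec.outcome == "skip") != (not rec.accepted):
        out.append(Violation(row, f"outcome={rec.outcome} inconsistent with accepted={rec.accepted}"))
    if rec.outcome == "skip" and rec.time_spent_s != 0:
        out.append(Violation(row, f"skip trial with time_spent_s={rec.time_spent_s} != 0"))
    if rec.outcome == "earn" and rec.time_spent_s != rec.offer_s:
        out.append(
            Violation(row, f"earn trial with time_spent_s={rec.time_spent_s} != offer_s={rec.offer_s}")
        )
    if rec.outcome == "quit" and not (1 <= rec.time_spent_s <= rec.offer_s - 1):
        out.append(
            Violation(
                row,
                f"quit trial with time_spent_s={rec.time_spent_s} outside [1, offer_s-1={rec.offer_s - 1}]",
            )
        )
    return out


@dataclass
class SessionSet:
    """An ordered collection of trials plus provenance metadata.

    Trials are stored as a :class:`pandas.DataFrame` with the schema columns;
    ``meta`` records where the data came from (generator name, config hash,
    seed, offer support).  Trials are independent — no cross-trial state.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def offer_support(self) -> tuple[int, int]:
        lo, hi = self.meta.get("offer_support", (1, 30))
        return int(lo), int(hi)

    def records(self) -> Iterator[TrialRecord]:
        for row in self.df.itertuples(index=False):
            w0 = None if pd.isna(row.w0) else float(row.w0)
            yield TrialRecord(
                subject_id=str(row.subject_id),
                session_id=str(row.session_id),
                site_id=str(row.site_id),
                offer_s=int(row.offer_s),
                accepted=bool(row.accepted),
                time_spent_s=int(row.time_spent_s),
                outcome=str(row.outcome),
                w0=w0,
            )

    @classmethod
    def from_records(cls, records: list[TrialRecord], meta: dict | None = None) -> "SessionSet":
        df = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "session_id": r.session_id,
                    "site_id": r.site_id,
                    "offer_s": r.offer_s,
                    "accepted": r.accepted,
                    "time_spent_s": r.time_spent_s,
                    "outcome": r.outcome,
                    "w0": np.nan if r.w0 is None else r.w0,
                }
                for r in records
            ],
            columns=CSV_COLUMNS,
        )
        return cls(df=df, meta=dict(meta or {}))


def validate_trials(data: SessionSet) -> list[Violation]:
    """Check every trial invariant; the empty list means the set is valid."""
    out: list[Violation] = []
    support = data.offer_support
    for i, rec in enumerate(data.records()):
        out.extend(_record_violations(rec, row=i, offer_support=support))
    return out


def _coerce_int_seconds(value: str, column: str, row: int) -> int:
    try:
        x = float(value)
    except ValueError as exc:
        raise SchemaError(f"row {row}: cannot parse {column}={value!r} as seconds") from exc
    floored = int(np.floor(x))
    if floored != x:
        warnings.warn(
            f"row {row}: non-integer {column}={x} floored to {floored} (1 s time grid)",
            stacklevel=3,
        )
    return floored


def read_trials_csv(path: str | Path, offer_support: tuple[int, int] = (1, 30)) -> SessionSet:
    """Read and validate a trial-log CSV; row order is preserved.

    Raises :class:`SchemaError` if a column is missing and
    :class:`TrialValidationError` (naming the first offending row) if any
    invariant fails.  A JSON sidecar ``<path>.meta.json``, if present, is
    loaded into ``meta``.
    """
    path = Path(path)
    rows: list[dict] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        for i, raw in enumerate(reader):
            w0_raw = (raw.get("w0") or "").strip()
            rows.append(
                {
                    "subject_id": raw["subject_id"],
                    "session_id": raw["session_id"],
                    "site_id": raw["site_id"],
                    "offer_s": _coerce_int_seconds(raw["offer_s"], "offer_s", i),
                    "accepted": raw["accepted"].strip() in ("1", "True", "true"),
                    "time_spent_s": _coerce_int_seconds(raw["time_spent_s"], "time_spent_s", i),
                    "outcome": raw["outcome"].strip(),
                    "w0": np.nan if w0_raw == "" else float(w0_raw),
                }
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    meta: dict = {"offer_support": list(offer_support)}
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    data = SessionSet(df=df, meta=meta)
    violations = validate_trials(data)
    if violations:
        v = violations[0]
        raise TrialValidationError(f"{path}: row {v.row}: {v.message}", row=v.row)
    return data


def write_trials_csv(data: SessionSet, path: str | Path) -> None:
    """Write a SessionSet to CSV plus a ``.meta.json`` sidecar.

    Round trip: ``read_trials_csv(write_trials_csv(x))`` reproduces ``x``
    field for field.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in data.records():
            writer.writerow(
                [
                    rec.subject_id,
                    rec.session_id,
                    rec.site_id,
                    rec.offer_s,
                    int(rec.accepted),
                    rec.time_spent_s,
                    rec.outcome,
                    "" if rec.w0 is None else repr(rec.w0),
                ]
            )
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(data.meta, indent=2, default=str) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for provenance metadata."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
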