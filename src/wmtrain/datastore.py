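"""Persistence: SQLite entity store, raw text logs, reports and export.

The store mirrors the app's three-section relational schema — *Patients*
(personal data and uninterpreted clinical metadata), *Exercises and
Treatments* (exercise records, assignments and the staircase bookkeeping)
and *Settings* (the single active configuration row) — in one SQLite file,
with primary keys and enforced foreign keys.

Raw trial data live outside the database as append-only, tab-separated
UTF-8 text files, one line per executed block, with ISO-8601 timestamps and
the full config snapshot plus the stimulus seed so any block can be
replayed.  Writer and reader are exact inverses.  A per-patient report
(date/time, paradigm, parameters, correct/incorrect/missed counts, level,
plus the per-exercise maximum level achieved) is regenerated from the raw
log on demand.  ``export_bundle``/``import_bundle`` move logs, reports and
entities between stores with a SHA-256 manifest guarding integrity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .adaptive import ExerciseRecord
from .errors import InputError, IntegrityError
from .exercises import (
    BlockResult,
    ExerciseType,
    config_from_dict,
    config_to_dict,
)

__all__ = [
    "Patient",
    "TreatmentAssignment",
    "Settings",
    "RawLogLine",
    "Store",
    "append_raw_log",
    "read_raw_log",
    "generate_report",
    "Report",
    "export_bundle",
    "import_bundle",
]


@dataclass(frozen=True)
class Patient:
    """Personal data row; clinical metadata is stored but never interpreted."""

    patient_id: str
    name: str = ""
    metadata: dict = field(default_factory=dict, hash=False)


@dataclass(frozen=True)
class TreatmentAssignment:
    """Links a patient to an exercise record at an ordinal position."""

    assignment_id: str
    patient_id: str
    record_id: str
    ordinal: int = 0
    adaptive_enabled: bool = True


@dataclass(frozen=True)
class Settings:
    """The single active configuration row.

    ``user_mode`` distinguishes the USER modality (patient-facing, restricted)
    from the ADMIN modality; here it is a pure flag affecting CLI affordances.
    """

    user_mode: bool = False
    program_name: str = "takeuchi-8w"
    thresholds: dict = field(default_factory=dict, hash=False)


# ---------------------------------------------------------------------------
# raw log

RAW_LOG_COLUMNS = (
    "timestamp",
    "patient_id",
    "exercise_type",
    "level",
    "config",
    "seed",
    "n_correct",
    "n_incorrect",
    "n_missed",
    "pct_correct",
    "valid",
)


@dataclass(frozen=True)
class RawLogLine:
    """One executed block as written to the raw text log."""

    timestamp: str  # ISO-8601
    patient_id: str
    exercise_type: ExerciseType
    level: int
    config: object
    seed: int
    n_correct: int
    n_incorrect: int
    n_missed: int
    pct_correct: float
    valid: bool

    def to_tsv(self) -> str:
        cfg = json.dumps(config_to_dict(self.config), sort_keys=True, separators=(",", ":"))
        fields = (
            self.timestamp,
            self.patient_id,
            self.exercise_type.value,
            str(self.level),
            cfg,
            str(self.seed),
            str(self.n_correct),
            str(self.n_incorrect),
            str(self.n_missed),
            repr(float(self.pct_correct)),
            "1" if self.valid else "0",
        )
        for f in fields:
            if "\t" in f or "\n" in f:
                raise InputError("raw log fields may not contain tabs or newlines")
        return "\t".join(fields)

    @classmethod
    def from_tsv(cls, line: str) -> "RawLogLine":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(RAW_LOG_COLUMNS):
            raise InputError(
                f"expected {len(RAW_LOG_COLUMNS)} tab-separated fields, got {len(parts)}"
            )
        (ts, pid, ext, level, cfg, seed, c, i, m, pct, valid) = parts
        # datetime.fromisoformat validates the timestamp format
        datetime.fromisoformat(ts)
        if valid not in ("0", "1"):
            raise InputError(f"valid flag must be 0 or 1, got {valid!r}")
        return cls(
            timestamp=ts,
            patient_id=pid,
            exercise_type=ExerciseType(ext),
            level=int(level),
            config=config_from_dict(json.loads(cfg)),
            seed=int(seed),
            n_correct=int(c),
            n_incorrect=int(i),
            n_missed=int(m),
            pct_correct=float(pct),
            valid=valid == "1",
        )


_HEADER = "\t".join(RAW_LOG_COLUMNS)


def append_raw_log(
    result: BlockResult,
    record: ExerciseRecord,
    path: str | Path,
    *,
    seed: int,
    valid: bool,
    timestamp: datetime | None = None,
) -> RawLogLine:
    """Append exactly one block line (writing the header on first use)."""
    path = Path(path)
    ts = timestamp or result.timestamp or datetime.now()
    line = RawLogLine(
        timestamp=ts.isoformat() if isinstance(ts, datetime) else str(ts),
        patient_id=record.patient_id or "",
        exercise_type=result.exercise_type,
        level=result.level,
        config=record.config,
        seed=seed,
        n_correct=result.n_correct,
        n_incorrect=result.n_incorrect,
        n_missed=result.n_missed,
        pct_correct=result.pct_correct,
        valid=valid,
    )
    text = line.to_tsv()  # serialise (and validate) before touching the file
    new = not path.exists() or path.stat().st_size == 0
    with open(path, "a", encoding="utf-8") as fh:
        if new:
            fh.write(_HEADER + "\n")
        fh.write(text + "\n")
    return line


def read_raw_log(path: str | Path):
    """Parse a raw log; malformed lines are reported, not fatal.

    Returns ``(lines, errors)`` where ``errors`` is a list of
    ``(line_number, message)`` (1-based, counting the header).
    """
    path = Path(path)
    lines: list[RawLogLine] = []
    errors: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    if not raw:
        return lines, errors
    if raw[0] != _HEADER:
        errors.append((1, "unrecognised header line"))
    for lineno, text in enumerate(raw[1:], start=2):
        if not text.strip():
            continue
        try:
            lines.append(RawLogLine.from_tsv(text))
        except Exception as exc:
            errors.append((lineno, str(exc)))
    return lines, errors


# ---------------------------------------------------------------------------
# store

_SCHEMA = """
CREATE TABLE IF NOT EXISTS patients (
    patient_id TEXT PRIMARY KEY,
    name TEXT NOT NULL DEFAULT '',
    metadata TEXT NOT NULL DEFAULT '{}'
);
CREATE TABLE IF NOT EXISTS records (
    record_id TEXT PRIMARY KEY,
    patient_id TEXT REFERENCES patients(patient_id),
    exercise_type TEXT NOT NULL,
    level INTEGER NOT NULL,
    config TEXT NOT NULL,
    auto_generated INTEGER NOT NULL DEFAULT 0,
    parent_record_id TEXT
);
CREATE TABLE IF NOT EXISTS assignments (
    assignment_id TEXT PRIMARY KEY,
    patient_id TEXT NOT NULL REFERENCES patients(patient_id),
    record_id TEXT NOT NULL REFERENCES records(record_id),
    ordinal INTEGER NOT NULL DEFAULT 0,
    adaptive_enabled INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE IF NOT EXISTS settings (
    id INTEGER PRIMARY KEY CHECK (id = 1),
    user_mode INTEGER NOT NULL DEFAULT 0,
    program_name TEXT NOT NULL DEFAULT 'takeuchi-8w',
    thresholds TEXT NOT NULL DEFAULT '{}'
);
"""


class Store:
    """Single-directory datastore: one SQLite file plus a raw-log folder."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.rawlog_dir = self.root / "rawlogs"
        self.rawlog_dir.mkdir(exist_ok=True)
        self.db_path = self.root / "store.db"
        self._conn = sqlite3.connect(self.db_path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- upserts ----------------------------------------------------------

    def upsert(self, entity):
        """Insert or replace an entity; returns it for chaining."""
        if isinstance(entity, Patient):
            self._conn.execute(
                "INSERT OR REPLACE INTO patients VALUES (?, ?, ?)",
                (entity.patient_id, entity.name, json.dumps(entity.metadata, sort_keys=True)),
            )
        elif isinstance(entity, ExerciseRecord):
            if entity.patient_id is not None and self._get_row(
                "patients", "patient_id", entity.patient_id
            ) is None:
                raise IntegrityError(f"record references unknown patient {entity.patient_id!r}")
            self._conn.execute(
                "INSERT OR REPLACE INTO records VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    entity.record_id,
                    entity.patient_id,
                    entity.exercise_type.value,
                    entity.level,
                    json.dumps(config_to_dict(entity.config), sort_keys=True),
                    int(entity.auto_generated),
                    entity.parent_record_id,
                ),
            )
        elif isinstance(entity, TreatmentAssignment):
            record = self.get_record(entity.record_id, missing_ok=True)
            if record is None:
                raise IntegrityError(f"assignment references unknown record {entity.record_id!r}")
            if self._get_row("patients", "patient_id", entity.patient_id) is None:
                raise IntegrityError(f"assignment references unknown patient {entity.patient_id!r}")
            if record.patient_id is not None and record.patient_id != entity.patient_id:
                raise IntegrityError(
                    f"record {record.record_id!r} is bound to patient "
                    f"{record.patient_id!r} and cannot be assigned to {entity.patient_id!r}"
                )
            self._conn.execute(
                "INSERT OR REPLACE INTO assignments VALUES (?, ?, ?, ?, ?)",
                (
                    entity.assignment_id,
                    entity.patient_id,
                    entity.record_id,
                    entity.ordinal,
                    int(entity.adaptive_enabled),
                ),
            )
        elif isinstance(entity, Settings):
            self._conn.execute(
                "INSERT OR REPLACE INTO settings VALUES (1, ?, ?, ?)",
                (
                    int(entity.user_mode),
                    entity.program_name,
                    json.dumps(entity.thresholds, sort_keys=True),
                ),
            )
        else:
            raise InputError(f"cannot store entity of type {type(entity).__name__}")
        self._conn.commit()
        return entity

    # -- getters ----------------------------------------------------------

    def _get_row(self, table: str, key: str, value):
        cur = self._conn.execute(f"SELECT * FROM {table} WHERE {key} = ?", (value,))
        return cur.fetchone()

    def get_patient(self, patient_id: str) -> Patient:
        row = self._get_row("patients", "patient_id", patient_id)
        if row is None:
            raise LookupError(f"unknown patient {patient_id!r}")
        return Patient(patient_id=row[0], name=row[1], metadata=json.loads(row[2]))

    def patients(self) -> list[Patient]:
        cur = self._conn.execute("SELECT patient_id FROM patients ORDER BY patient_id")
        return [self.get_patient(r[0]) for r in cur.fetchall()]

    def get_record(self, record_id: str, missing_ok: bool = False) -> ExerciseRecord | None:
        row = self._get_row("records", "record_id", record_id)
        if row is None:
            if missing_ok:
                return None
            raise LookupError(f"unknown record {record_id!r}")
        return ExerciseRecord(
            record_id=row[0],
            patient_id=row[1],
            exercise_type=ExerciseType(row[2]),
            level=row[3],
            config=config_from_dict(json.loads(row[4])),
            auto_generated=bool(row[5]),
            parent_record_id=row[6],
        )

    def records(self) -> list[ExerciseRecord]:
        cur = self._conn.execute("SELECT record_id FROM records ORDER BY record_id")
        return [self.get_record(r[0]) for r in cur.fetchall()]

    def get_assignment(self, assignment_id: str) -> TreatmentAssignment:
        row = self._get_row("assignments", "assignment_id", assignment_id)
        if row is None:
            raise LookupError(f"unknown assignment {assignment_id!r}")
        return TreatmentAssignment(
            assignment_id=row[0],
            patient_id=row[1],
            record_id=row[2],
            ordinal=row[3],
            adaptive_enabled=bool(row[4]),
        )

    def assignments(self) -> list[TreatmentAssignment]:
        cur = self._conn.execute("SELECT assignment_id FROM assignments ORDER BY assignment_id")
        return [self.get_assignment(r[0]) for r in cur.fetchall()]

    def get_settings(self) -> Settings | None:
        row = self._get_row("settings", "id", 1)
        if row is None:
            return None
        return Settings(
            user_mode=bool(row[1]), program_name=row[2], thresholds=json.loads(row[3])
        )

    # -- raw logs ---------------------------------------------------------

    def raw_log_path(self, patient_id: str) -> Path:
        return self.rawlog_dir / f"{patient_id}.tsv"

    def log_block(
        self,
        result: BlockResult,
        record: ExerciseRecord,
        *,
        seed: int,
        valid: bool,
        timestamp: datetime | None = None,
    ) -> RawLogLine:
        if record.patient_id is None:
            raise IntegrityError("cannot log a block for an unassigned record")
        return append_raw_log(
            result,
            record,
            self.raw_log_path(record.patient_id),
            seed=seed,
            valid=valid,
            timestamp=timestamp,
        )

    def read_log(self, patient_id: str):
        path = self.raw_log_path(patient_id)
        if not path.exists():
            return [], []
        return read_raw_log(path)

    # -- snapshot for equality / export ----------------------------------

    def snapshot(self) -> dict:
        """Deterministic dict of all entities and raw log texts."""
        logs = {}
        for p in sorted(self.rawlog_dir.glob("*.tsv")):
            logs[p.name] = p.read_text(encoding="utf-8")
        return {
            "patients": [dataclasses.asdict(p) for p in self.patients()],
            "records": [
                {**dataclasses.asdict(r), "exercise_type": r.exercise_type.value,
                 "config": config_to_dict(r.config)}
                for r in self.records()
            ],
            "assignments": [dataclasses.asdict(a) for a in self.assignments()],
            "settings": dataclasses.asdict(self.get_settings()) if self.get_settings() else None,
            "rawlogs": logs,
        }


# ---------------------------------------------------------------------------
# report


@dataclass
class Report:
    """Per-patient processed-data report regenerated from the raw log."""

    patient_id: str
    rows: list[RawLogLine]
    max_levels: dict[ExerciseType, int]

    def to_frame(self) -> pd.DataFrame:
        data = [
            {
                "timestamp": r.timestamp,
                "exercise_type": r.exercise_type.value,
                "description": r.exercise_type.description,
                "parameters": json.dumps(config_to_dict(r.config), sort_keys=True),
                "level": r.level,
                "n_correct": r.n_correct,
                "n_incorrect": r.n_incorrect,
                "n_missed": r.n_missed,
                "pct_correct": r.pct_correct,
                "valid": r.valid,
            }
            for r in self.rows
        ]
        return pd.DataFrame(
            data,
            columns=[
                "timestamp", "exercise_type", "description", "parameters", "level",
                "n_correct", "n_incorrect", "n_missed", "pct_correct", "valid",
            ],
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_text(self) -> str:
        lines = [f"Report for patient {self.patient_id}", ""]
        if not self.rows:
            lines.append("No blocks executed.")
            return "\n".join(lines) + "\n"
        for r in self.rows:
            lines.append(
                f"{r.timestamp}  {r.exercise_type.value:6s} level {r.level:>2d}  "
                f"correct {r.n_correct:>2d}  incorrect {r.n_incorrect:>2d}  "
                f"missed {r.n_missed:>2d}  ({r.pct_correct:.1f}% "
                f"{'valid' if r.valid else 'not valid'})"
            )
        lines.append("")
        for t, lvl in sorted(self.max_levels.items(), key=lambda kv: kv[0].value):
            lines.append(f"Maximum level achieved in {t.value}: {lvl}")
        return "\n".join(lines) + "\n"


def generate_report(patient_id: str, store: Store) -> Report:
    """Rebuild the per-patient report from the raw log (patient must exist)."""
    store.get_patient(patient_id)  # raises LookupError if unknown
    rows, errors = store.read_log(patient_id)
    if errors:
        raise IntegrityError(
            f"raw log for {patient_id!r} contains malformed lines: {errors[:3]}"
        )
    max_levels: dict[ExerciseType, int] = {}
    for r in rows:
        cur = max_levels.get(r.exercise_type)
        if cur is None or r.level > cur:
            max_levels[r.exercise_type] = r.level
    return Report(patient_id=patient_id, rows=rows, max_levels=max_levels)


# ---------------------------------------------------------------------------
# export / import


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_bundle(store: Store, destination: str | Path) -> Path:
    """Write raw logs, reports and entities to a checksummed bundle directory."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    (dest / "rawlogs").mkdir(exist_ok=True)
    (dest / "reports").mkdir(exist_ok=True)
    snap = store.snapshot()
    written: list[Path] = []
    for name, key in (
        ("patients.json", "patients"),
        ("records.json", "records"),
        ("assignments.json", "assignments"),
        ("settings.json", "settings"),
    ):
        p = dest / name
        p.write_text(json.dumps(snap[key], indent=1, sort_keys=True), encoding="utf-8")
        written.append(p)
    for logname, text in snap["rawlogs"].items():
        p = dest / "rawlogs" / logname
        p.write_text(text, encoding="utf-8")
        written.append(p)
    for patient in store.patients():
        report = generate_report(patient.patient_id, store)
        p = dest / "reports" / f"report_{patient.patient_id}.tsv"
        p.write_text(report.to_tsv(), encoding="utf-8")
        written.append(p)
    manifest = {str(p.relative_to(dest)): _sha256(p) for p in written}
    (dest / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return dest


def import_bundle(bundle: str | Path, store: Store) -> Store:
    """Verify a bundle's checksums and load its contents into ``store``."""
    bundle = Path(bundle)
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError("bundle has no manifest.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    for rel, digest in manifest.items():
        p = bundle / rel
        if not p.exists():
            raise IntegrityError(f"bundle file {rel} is missing")
        if _sha256(p) != digest:
            raise IntegrityError(f"bundle file {rel} fails its checksum")
    patients = json.loads((bundle / "patients.json").read_text(encoding="utf-8"))
    for p in patients:
        store.upsert(Patient(**p))
    records = json.loads((bundle / "records.json").read_text(encoding="utf-8"))
    for r in sorted(records, key=lambda r: (r["parent_record_id"] is not None, r["record_id"])):
        store.upsert(
            ExerciseRecord(
                record_id=r["record_id"],
                patient_id=r["patient_id"],
                exercise_type=ExerciseType(r["exercise_type"]),
                level=r["level"],
                config=config_from_dict(r["config"]),
                auto_generated=r["auto_generated"],
                parent_record_id=r["parent_record_id"],
            )
        )
    assignments = json.loads((bundle / "assignments.json").read_text(encoding="utf-8"))
    for a in assignments:
        store.upsert(TreatmentAssignment(**a))
    settings = json.loads((bundle / "settings.json").read_text(encoding="utf-8"))
    if settings is not None:
        store.upsert(Settings(**settings))
    src_logs = bundle / "rawlogs"
    if src_logs.exists():
        for p in sorted(src_logs.glob("*.tsv")):
            shutil.copyfile(p, store.rawlog_dir / p.name)
    return store
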