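"""Readers and writers for sequence-level sleep exports.

Two dialects are supported:

* **csv** — one row per segment with header
  ``person_id,start_datetime,duration_seconds,level,log_id,is_main_sleep``
  (ISO-8601 local timestamps; the last two columns may be blank).
  Lines starting with ``#`` are treated as provenance comments.
* **json** — the Fitbit Web API sleep-log shape: a top-level ``sleep``
  array whose entries carry ``logId``, ``isMainSleep`` and a nested
  ``levels.data`` array of ``{dateTime, level, seconds}`` segments.

Both dialects round-trip losslessly through :func:`write_segments` /
:func:`read_segments`.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    ALL_LEVELS,
    SchemaError,
    SleepLog,
    SleepSegment,
    ValidationError,
)

CSV_COLUMNS = ["person_id", "start_datetime", "duration_seconds", "level",
               "log_id", "is_main_sleep"]

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def read_segments(path: str | Path, dialect: str = "csv") -> list[SleepSegment]:
    """Read and validate segments from a file.

    Invalid rows are rejected collectively: a :class:`ValidationError`
    listing offending line numbers is raised, never a silent drop.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "json":
        return _read_json(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> list[SleepSegment]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    segments: list[SleepSegment] = []
    errors: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            duration = int(getattr(row, "duration_seconds"))
            start = datetime.fromisoformat(getattr(row, "start_datetime"))
            level = getattr(row, "level")
            if level not in ALL_LEVELS:
                raise ValidationError(f"unknown level {level!r}")
            log_id = getattr(row, "log_id", "") or None
            is_main = _parse_bool(getattr(row, "is_main_sleep", "") or None)
            segments.append(SleepSegment(
                person_id=str(getattr(row, "person_id")),
                start=start, duration_s=duration, level=level,
                source_log_id=log_id, source_is_main=is_main,
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid rows\n" + "\n".join(errors))
    return segments


def _read_json(path: Path) -> list[SleepSegment]:
    payload = json.loads(path.read_text())
    if "sleep" not in payload:
        raise SchemaError(f"{path}: missing top-level 'sleep' array")
    default_person = payload.get("person_id")
    segments: list[SleepSegment] = []
    errors: list[str] = []
    for li, log in enumerate(payload["sleep"]):
        person = str(log.get("person_id", default_person))
        log_id = log.get("logId")
        is_main = log.get("isMainSleep")
        data = (log.get("levels") or {}).get("data")
        if data is None:
            errors.append(f"sleep[{li}]: missing levels.data")
            continue
        for si, rec in enumerate(data):
            try:
                level = rec["level"]
                if level not in ALL_LEVELS:
                    raise ValidationError(f"unknown level {level!r}")
                segments.append(SleepSegment(
                    person_id=person,
                    start=datetime.fromisoformat(rec["dateTime"]),
                    duration_s=int(rec["seconds"]),
                    level=level,
                    source_log_id=str(log_id) if log_id is not None else None,
                    source_is_main=bool(is_main) if is_main is not None else None,
                ))
            except (KeyError, ValueError, TypeError) as exc:
                errors.append(f"sleep[{li}].levels.data[{si}]: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid records\n" + "\n".join(errors))
    return segments


def segments_to_frame(segments: Sequence[SleepSegment]) -> pd.DataFrame:
    rows = [{
        "person_id": s.person_id,
        "start_datetime": s.start.strftime(_TS_FMT),
        "duration_seconds": s.duration_s,
        "level": s.level,
        "log_id": s.source_log_id if s.source_log_id is not None else "",
        "is_main_sleep": "" if s.source_is_main is None else str(s.source_is_main).lower(),
    } for s in segments]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_segments(segments: Sequence[SleepSegment], path: str | Path,
                   dialect: str = "csv",
                   provenance: Optional[dict] = None) -> Path:
    """Serialize segments; deterministic, byte-identical for equal input."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "csv":
        header = ""
        if provenance:
            header = "".join(f"# {k}: {v}\n" for k, v in sorted(provenance.items()))
        path.write_text(header + segments_to_frame(segments).to_csv(index=False))
    elif dialect == "json":
        path.write_text(json.dumps(_segments_to_api_json(segments), indent=1,
                                   sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _segments_to_api_json(segments: Sequence[SleepSegment]) -> dict:
    # group by (person, source log id); segments without one each form a group
    groups: dict[tuple, list[SleepSegment]] = {}
    for i, s in enumerate(sorted(segments, key=lambda s: (s.person_id, s.start))):
        key = (s.person_id, s.source_log_id if s.source_log_id is not None else f"_anon{i}")
        groups.setdefault(key, []).append(s)
    sleep = []
    for (person, log_id), segs in groups.items():
        is_main = segs[0].source_is_main
        entry = {
            "person_id": person,
            "levels": {"data": [{
                "dateTime": s.start.strftime(_TS_FMT),
                "level": s.level,
                "seconds": s.duration_s,
            } for s in segs]},
        }
        if not str(log_id).startswith("_anon"):
            entry["logId"] = log_id
        if is_main is not None:
            entry["isMainSleep"] = is_main
        sleep.append(entry)
    return {"sleep": sleep}


def write_logs(logs: Sequence[SleepLog], path: str | Path,
               provenance: Optional[dict] = None) -> Path:
    """Write reconstructed logs as segment rows keyed by log id.

    ``read_logs(write_logs(x)) == x`` field-by-field: grouping on read
    uses the stored log id, not the gap rule, so hybrid logs and
    per-segment levels survive unchanged.
    """
    flat = []
    for lg in logs:
        for s in lg.segments:
            flat.append(SleepSegment(s.person_id, s.start, s.duration_s, s.level,
                                     source_log_id=lg.log_id,
                                     source_is_main=s.source_is_main))
    return write_segments(flat, path, dialect="csv", provenance=provenance)


def read_logs(path: str | Path) -> list[SleepLog]:
    """Inverse of :func:`write_logs`; groups rows by their log id column."""
    segments = read_segments(path, dialect="csv")
    groups: dict[str, list[SleepSegment]] = {}
    for s in segments:
        if s.source_log_id is None:
            raise SchemaError(f"{path}: log_id column required to read logs")
        groups.setdefault(s.source_log_id, []).append(s)
    logs = [SleepLog(log_id, segs[0].person_id, segs) for log_id, segs in groups.items()]
    return sorted(logs, key=lambda lg: (lg.person_id, lg.start))
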