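"""Readers and writers for the workflow's file formats.

Formats (all plain text):

* event log CSV/JSONL — ``timestamp, event_type, app_id`` (see ``events``);
* daily summary CSV — one row per participant-night from detection,
  missing nights included with empty indicator fields;
* self-report CSV — ``participant_id, wake_date, onset, wake``;
* ground-truth CSV — same plus the self-report columns (simulator output);
* provenance JSON — config hash, seed and package version for each run.

Writers and readers round-trip: reading back a written file reproduces the
in-memory objects.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .config import RunConfig, config_hash
from .events import RawEvent
from .exceptions import EventLogError
from .simulate import CohortSim
from .sleep import SleepRecord, SleepSeries, make_sleep_record

__all__ = [
    "write_event_log",
    "write_daily_summary",
    "read_daily_summary",
    "write_self_reports",
    "read_sleep_csv",
    "write_ground_truth",
    "write_cohort",
    "write_provenance",
]

_SUMMARY_COLUMNS = [
    "participant_id",
    "wake_date",
    "onset",
    "wake",
    "midpoint",
    "tst_seconds",
    "onset_extended",
    "wake_extended",
    "n_candidate_episodes",
    "tie_flag",
]


def _iso(dt: datetime) -> str:
    return dt.isoformat(sep=" ")


def write_event_log(
    events: Sequence[RawEvent], path: str | Path, fmt: str = "csv"
) -> None:
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp", "event_type", "app_id"])
            for ev in events:
                writer.writerow([_iso(ev.timestamp), ev.event_type, ev.app_id or ""])
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for ev in events:
                fh.write(
                    json.dumps(
                        {
                            "timestamp": _iso(ev.timestamp),
                            "event_type": ev.event_type,
                            "app_id": ev.app_id or "",
                        }
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown event-log format {fmt!r}")


def write_daily_summary(series_list: Sequence[SleepSeries], path: str | Path) -> None:
    """One row per participant-night; missing nights keep empty indicators."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SUMMARY_COLUMNS)
        for series in series_list:
            rows: list[tuple[date, SleepRecord | None]] = [
                (r.wake_date, r) for r in series.records
            ] + [(d, None) for d in series.missing_nights]
            for wake_date, rec in sorted(rows, key=lambda x: x[0]):
                if rec is None:
                    writer.writerow(
                        [series.participant_id, wake_date.isoformat()] + [""] * 8
                    )
                else:
                    writer.writerow(
                        [
                            series.participant_id,
                            wake_date.isoformat(),
                            _iso(rec.onset),
                            _iso(rec.wake),
                            _iso(rec.midpoint),
                            rec.tst_s,
                            int(rec.onset_extended),
                            int(rec.wake_extended),
                            rec.n_candidates,
                            int(rec.tie),
                        ]
                    )


def read_daily_summary(path: str | Path) -> list[SleepSeries]:
    """Read a daily summary back into per-participant series."""
    per_part: dict[str, tuple[list[SleepRecord], list[date]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pid = row["participant_id"]
            records, missing = per_part.setdefault(pid, ([], []))
            wake_date = date.fromisoformat(row["wake_date"])
            if not row["onset"]:
                missing.append(wake_date)
                continue
            records.append(
                SleepRecord(
                    wake_date=wake_date,
                    onset=datetime.fromisoformat(row["onset"]),
                    wake=datetime.fromisoformat(row["wake"]),
                    midpoint=datetime.fromisoformat(row["midpoint"]),
                    tst_s=int(row["tst_seconds"]),
                    onset_extended=bool(int(row["onset_extended"])),
                    wake_extended=bool(int(row["wake_extended"])),
                    n_candidates=int(row["n_candidate_episodes"]),
                    tie=bool(int(row["tie_flag"])),
                )
            )
    return [
        SleepSeries(pid, records, missing)
        for pid, (records, missing) in sorted(per_part.items())
    ]


def write_self_reports(cohort: CohortSim, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "wake_date", "onset", "wake"])
        for part in cohort.participants:
            for night in part.truth:
                writer.writerow(
                    [
                        part.participant_id,
                        night.wake_date.isoformat(),
                        _iso(night.self_onset),
                        _iso(night.self_wake),
                    ]
                )


def read_sleep_csv(path: str | Path, source: str = "self_report") -> list[SleepSeries]:
    """Read ``participant_id, wake_date, onset, wake`` rows into series."""
    per_part: dict[str, list[SleepRecord]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "wake_date", "onset", "wake"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise EventLogError(
                f"{path}: expected columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            rec = make_sleep_record(
                onset=datetime.fromisoformat(row["onset"]),
                wake=datetime.fromisoformat(row["wake"]),
                wake_date=date.fromisoformat(row["wake_date"]),
                source=source,
            )
            per_part.setdefault(row["participant_id"], []).append(rec)
    return [
        SleepSeries(pid, sorted(records, key=lambda r: r.wake_date))
        for pid, records in sorted(per_part.items())
    ]


def write_ground_truth(cohort: CohortSim, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "participant_id",
                "wake_date",
                "onset",
                "wake",
                "tst_seconds",
                "self_onset",
                "self_wake",
            ]
        )
        for part in cohort.participants:
            for night in part.truth:
                writer.writerow(
                    [
                        part.participant_id,
                        night.wake_date.isoformat(),
                        _iso(night.onset),
                        _iso(night.wake),
                        night.tst_s,
                        _iso(night.self_onset),
                        _iso(night.self_wake),
                    ]
                )


def write_cohort(cohort: CohortSim, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write event logs (one file per participant), ground truth and self-reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for part in cohort.participants:
        ext = "csv" if fmt == "csv" else "jsonl"
        p = out / f"events_{part.participant_id}.{ext}"
        write_event_log(part.events, p, fmt)
        written.append(p)
    truth_path = out / "ground_truth.csv"
    write_ground_truth(cohort, truth_path)
    written.append(truth_path)
    sr_path = out / "self_report.csv"
    write_self_reports(cohort, sr_path)
    written.append(sr_path)
    return written


def write_provenance(
    out_dir: str | Path, config: RunConfig, extra: dict | None = None
) -> Path:
    """Machine-readable record of what produced a run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    block = {
        "tool": "rhythmkit",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
    }
    if extra:
        block.update(extra)
    path = out / "provenance.json"
    path.write_text(json.dumps(block, indent=2, sort_keys=True) + "\n")
    return path
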