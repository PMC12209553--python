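"""Reading and writing event-history and counting-process CSV files.

The event-history dialect is one CSV holding both the subject roster
and the events:

* roster rows — one per subject — carry ``subject_id``, ``cluster_id``,
  ``arm``, ``followup_end`` and any covariate columns, with
  ``event_time`` empty;
* event rows carry ``subject_id`` and ``event_time`` (other fields may
  repeat the roster values or stay empty).

Times are day offsets from the analysis-period start; ISO-8601 dates
are accepted when a ``date_origin`` is supplied and converted to day
offsets.  Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dataprep import CountingProcessTable, SubjectEventHistory

__all__ = [
    "read_event_histories",
    "write_event_histories",
    "read_counting_process",
    "write_counting_process",
]

ROSTER_FIELDS = ["subject_id", "cluster_id", "arm", "followup_end"]


def _to_days(value, origin: Optional[pd.Timestamp], line: int, column: str) -> float:
    if pd.isna(value) or value == "":
        return np.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    if origin is None:
        raise ValueError(
            f"line {line}: {column}={value!r} is not numeric and no date origin given"
        )
    try:
        return float((pd.Timestamp(value) - origin).days)
    except ValueError as exc:
        raise ValueError(f"line {line}: cannot parse {column}={value!r}") from exc


def read_event_histories(
    path, date_origin: Optional[str] = None
) -> list[SubjectEventHistory]:
    """Load validated subject event histories from the CSV dialect above."""
    origin = pd.Timestamp(date_origin) if date_origin else None
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("subject_id", "event_time"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    cov_cols = [c for c in df.columns if c not in ROSTER_FIELDS + ["event_time"]]
    roster: dict[str, dict] = {}
    events: dict[str, list[float]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rec = row._asdict()
        sid = rec["subject_id"]
        if not sid:
            raise ValueError(f"line {i}: empty subject_id")
        t = _to_days(rec["event_time"], origin, i, "event_time")
        if not np.isnan(t):
            events.setdefault(sid, []).append(t)
            if rec.get("followup_end", "") == "":
                continue  # pure event row
        if rec.get("followup_end", "") != "":
            if sid in roster:
                raise ValueError(f"line {i}: duplicate roster row for subject {sid!r}")
            if rec.get("cluster_id", "") == "":
                raise ValueError(f"line {i}: roster row missing cluster_id")
            try:
                arm = int(float(rec["arm"]))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"line {i}: invalid arm value") from exc
            cov = {}
            for c in cov_cols:
                if rec.get(c, "") != "":
                    try:
                        cov[c] = float(rec[c])
                    except ValueError as exc:
                        raise ValueError(
                            f"line {i}: covariate {c}={rec[c]!r} not numeric"
                        ) from exc
            roster[sid] = dict(
                cluster_id=rec["cluster_id"],
                arm=arm,
                followup_end=_to_days(rec["followup_end"], origin, i, "followup_end"),
                covariates=cov,
            )
    missing = sorted(set(events) - set(roster))
    if missing:
        raise ValueError(f"events for subjects without roster rows: {missing[:5]}")
    out = []
    for sid, info in roster.items():
        h = SubjectEventHistory(
            subject_id=sid,
            cluster_id=info["cluster_id"],
            arm=info["arm"],
            event_times=sorted(events.get(sid, [])),
            followup_end=info["followup_end"],
            covariates=info["covariates"],
        )
        out.append(h.validate())
    if not out:
        raise ValueError("no subjects found")
    return out


def write_event_histories(histories: Iterable[SubjectEventHistory], path) -> None:
    """Write histories in the same dialect ``read_event_histories`` reads."""
    rows = []
    for h in histories:
        base = {
            "subject_id": h.subject_id,
            "cluster_id": h.cluster_id,
            "arm": h.arm,
            "followup_end": h.followup_end,
            "event_time": "",
        }
        base.update(h.covariates)
        rows.append(base)
        for t in h.event_times:
            rows.append({"subject_id": h.subject_id, "event_time": t})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_counting_process(table: CountingProcessTable, path) -> None:
    df = table.data.copy()
    df.attrs = {}
    df.to_csv(path, index=False)
    # clock recorded in a sidecar comment line is fragile; keep it in the name
    # of the caller's config instead


def read_counting_process(path, clock: str) -> CountingProcessTable:
    df = pd.read_csv(path)
    needed = {"subject_id", "cluster_id", "stratum", "start", "stop", "status", "arm"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    cov = [c for c in df.columns if c not in needed]
    table = CountingProcessTable(df, clock, cov)
    table.validate()
    return table
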