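"""Counting-process data preparation for recurrent-event analysis.

Raw per-participant event histories are converted into the long
(start, stop] format used by stratified Cox intensity models: one row
per risk interval, stratified by cumulative event number, with a
conditional risk-set structure (a participant is not at risk of event k
until after event k-1).  Risk-set tabulation, event-count summaries and
truncation of sparse later-event strata live here as well.

Intervals are half-open (start, stop] with the event placed at ``stop``;
times are in days from the analysis-period start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectEventHistory",
    "CountingProcessTable",
    "EventCountSummary",
    "RiskSetSummary",
    "build_counting_process",
    "summarize_event_counts",
    "tabulate_risk_sets",
    "compute_truncation_points",
    "truncate_events",
]

CP_COLUMNS = [
    "subject_id",
    "cluster_id",
    "stratum",
    "start",
    "stop",
    "status",
    "arm",
]


@dataclass
class SubjectEventHistory:
    """One participant's observed event history.

    Parameters
    ----------
    subject_id, cluster_id : hashable
        Participant and cluster (e.g. GP practice) identifiers.
    arm : int
        Binary treatment indicator, 1 = intervention, 0 = control.
        Constant within a cluster (cluster randomisation).
    event_times : sequence of float
        Ordered event times in days from the analysis-period start.
    followup_end : float
        Time at which observation stops: the minimum of the analysis
        window end and the cluster's data cut-off.  Must be positive.
    covariates : dict
        Named baseline covariate values (age, sex, prior-period count, ...).
    """

    subject_id: object
    cluster_id: object
    arm: int
    event_times: Sequence[float]
    followup_end: float
    covariates: dict = field(default_factory=dict)

    def validate(self, tie_policy: str = "collapse") -> "SubjectEventHistory":
        """Check invariants, resolving same-day ties per ``tie_policy``.

        ``collapse`` merges duplicate times into one event; ``spread``
        distributes d tied events at equal sub-day increments within
        the day.  Returns a new, validated history.
        """
        if self.arm not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: arm must be 0 or 1")
        if not np.isfinite(self.followup_end) or self.followup_end <= 0:
            raise ValueError(
                f"subject {self.subject_id}: followup_end must be positive"
            )
        times = np.asarray(self.event_times, dtype=float)
        if times.size and times.min() < 0:
            raise ValueError(f"subject {self.subject_id}: negative event time")
        if np.any(times > self.followup_end):
            raise ValueError(
                f"subject {self.subject_id}: event time beyond followup_end"
            )
        times = np.sort(times)
        if times.size and np.any(np.diff(times) == 0):
            times = _resolve_ties(times, tie_policy)
        return SubjectEventHistory(
            self.subject_id,
            self.cluster_id,
            self.arm,
            times.tolist(),
            float(self.followup_end),
            dict(self.covariates),
        )


def _resolve_ties(times: np.ndarray, policy: str) -> np.ndarray:
    if policy == "collapse":
        return np.unique(times)
    if policy == "spread":
        out = []
        uniq, counts = np.unique(times, return_counts=True)
        for t, d in zip(uniq, counts):
            if d == 1:
                out.append(t)
            else:
                # spread d tied events at equal sub-day increments within [t, t+1)
                out.extend(t + np.arange(d) / d)
        return np.asarray(out)
    raise ValueError(f"unknown tie policy {policy!r}")


@dataclass
class CountingProcessTable:
    """Long-format risk-interval table plus the clock it was built on."""

    data: pd.DataFrame
    clock: Literal["gap", "total"]
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_events(self) -> int:
        return int(self.data["status"].sum())

    def strata_sizes(self) -> pd.Series:
        """Number of subjects at risk (rows) per stratum."""
        return self.data.groupby("stratum").size()

    def validate(self) -> None:
        df = self.data
        if (df["stop"] <= df["start"]).any():
            raise ValueError("zero- or negative-length risk interval")
        for sid, grp in df.groupby("subject_id", sort=False):
            strata = np.sort(grp["stratum"].to_numpy())
            if not np.array_equal(strata, np.arange(1, len(strata) + 1)):
                raise ValueError(f"subject {sid}: stratum numbers not 1..K")
            grp = grp.sort_values("stratum")
            status = grp["status"].to_numpy()
            if np.any(status[:-1] != 1):
                raise ValueError(
                    f"subject {sid}: non-terminal censored row "
                    "(conditional risk set violated)"
                )
        if self.clock == "gap" and (df["start"] != 0).any():
            raise ValueError("gap clock requires start = 0 on every row")


@dataclass
class EventCountSummary:
    """Counts/proportions of subjects with 0, 1 and >=2 events."""

    n_subjects: int
    zero: int
    one: int
    multiple: int
    total_events: int

    @property
    def proportions(self) -> dict:
        n = self.n_subjects
        return {"zero": self.zero / n, "one": self.one / n, "multiple": self.multiple / n}

    def to_frame(self) -> pd.DataFrame:
        p = self.proportions
        return pd.DataFrame(
            {
                "category": ["zero", "one", "multiple"],
                "count": [self.zero, self.one, self.multiple],
                "proportion": [p["zero"], p["one"], p["multiple"]],
            }
        )


@dataclass
class RiskSetSummary:
    """Per (stratum, arm) risk tabulation mirroring a number-at-risk table."""

    data: pd.DataFrame
    time_points: list[float]


def build_counting_process(
    histories: Iterable[SubjectEventHistory],
    window_end: float,
    clock: Literal["gap", "total"] = "gap",
    tie_policy: str = "collapse",
) -> CountingProcessTable:
    """Convert event histories into stratified (start, stop] rows.

    Each event inside the window yields a status-1 row in stratum k (its
    cumulative event number); observation ending after the last event
    yields one terminal status-0 row.  Subjects with zero events appear
    as a single censored row for stratum 1.  Under the ``gap`` clock all
    rows start at 0 and ``stop`` is the time since the previous event;
    under the ``total`` clock rows run on study time with delayed entry.
    A terminal censored row is emitted only when min(followup_end,
    window_end) strictly exceeds the last event time (no zero-length
    intervals).
    """
    if window_end <= 0:
        raise ValueError("window_end must be positive")
    rows = []
    cov_names: list[str] = []
    seen = set()
    for h in histories:
        h = h.validate(tie_policy)
        if h.subject_id in seen:
            raise ValueError(f"duplicate subject ID {h.subject_id!r}")
        seen.add(h.subject_id)
        for name in h.covariates:
            if name not in cov_names:
                cov_names.append(name)
        end = min(h.followup_end, window_end)
        times = [t for t in h.event_times if t <= window_end]
        prev = 0.0
        k = 0
        for k, t in enumerate(times, start=1):
            start, stop = (0.0, t - prev) if clock == "gap" else (prev, t)
            rows.append(_row(h, k, start, stop, 1))
            prev = t
        if end > prev:  # terminal censored interval has positive length
            start, stop = (0.0, end - prev) if clock == "gap" else (prev, end)
            rows.append(_row(h, k + 1, start, stop, 0))
    if not rows:
        raise ValueError("no risk intervals produced (empty input?)")
    df = pd.DataFrame(rows)
    for name in cov_names:
        if name not in df:
            df[name] = np.nan
    df = df[CP_COLUMNS + cov_names]
    table = CountingProcessTable(df, clock, cov_names)
    table.validate()
    return table


def _row(h: SubjectEventHistory, k: int, start: float, stop: float, status: int) -> dict:
    d = {
        "subject_id": h.subject_id,
        "cluster_id": h.cluster_id,
        "stratum": k,
        "start": start,
        "stop": stop,
        "status": status,
        "arm": h.arm,
    }
    d.update(h.covariates)
    return d


def summarize_event_counts(
    histories: Iterable[SubjectEventHistory], window_end: float
) -> EventCountSummary:
    """Counts of subjects with a maximum of zero, one and multiple events."""
    counts = []
    for h in histories:
        h = h.validate()
        counts.append(sum(1 for t in h.event_times if t <= window_end))
    if not counts:
        raise ValueError("empty population")
    counts = np.asarray(counts)
    return EventCountSummary(
        n_subjects=len(counts),
        zero=int((counts == 0).sum()),
        one=int((counts == 1).sum()),
        multiple=int((counts >= 2).sum()),
        total_events=int(counts.sum()),
    )


def tabulate_risk_sets(
    table: CountingProcessTable, time_points: Sequence[float]
) -> RiskSetSummary:
    """Number at risk, censored and cumulative events per (stratum, arm).

    The number at risk for stratum k is the conditional risk set: all
    subjects with at least k-1 events (the full population for k = 1).
    Zero-event subjects are reported as censored at 0 days in stratum 1;
    subjects censored after at least one event are reported as censored
    during follow-up in the stratum of their terminal row.  Cumulative
    event counts are taken on the stratum's own clock (gap times under
    the gap clock).
    """
    df = table.data
    window = float(df["stop"].max())
    for tp in time_points:
        if tp < 0 or tp > window:
            raise ValueError(f"time point {tp} outside the observation window")
    recs = []
    for (k, arm), grp in df.groupby(["stratum", "arm"]):
        at_risk = len(grp)
        cens = grp[grp["status"] == 0]
        censored_at_zero = len(cens) if k == 1 else 0
        censored_during = 0 if k == 1 else len(cens)
        rec = {
            "stratum": k,
            "arm": arm,
            "at_risk": at_risk,
            "censored_at_zero": censored_at_zero,
            "censored_during": censored_during,
        }
        ev = grp[grp["status"] == 1]
        for tp in time_points:
            rec[f"events_by_{tp:g}"] = int((ev["stop"] <= tp).sum())
        recs.append(rec)
    out = pd.DataFrame(recs).sort_values(["stratum", "arm"]).reset_index(drop=True)
    return RiskSetSummary(out, list(time_points))


def compute_truncation_points(
    population_size: int, fractions: Sequence[float]
) -> list[int]:
    """Participant-count thresholds: floor(fraction x population).

    Truncation keeps only strata whose risk set *strictly* exceeds the
    threshold (e.g. 5% of 11,564 participants gives "> 578").
    """
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    out = []
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fraction {f} not in (0, 1)")
        out.append(int(np.floor(f * population_size)))
    return out


def max_stratum_for_threshold(table: CountingProcessTable, threshold: int) -> int:
    """Largest stratum whose risk set strictly exceeds ``threshold``.

    Always at least 1 so the model retains every subject's first interval.
    """
    sizes = table.strata_sizes()
    keep = sizes[sizes > threshold]
    return int(keep.index.max()) if len(keep) else 1


def truncate_events(
    table: CountingProcessTable, max_stratum: int
) -> CountingProcessTable:
    """Cap events per participant: drop all rows with stratum > max_stratum.

    Retained rows are unchanged (including status: a subject whose row at
    ``max_stratum`` ends in an event keeps it as an event row).  Every
    subject is retained, since all have a stratum-1 row.
    """
    if max_stratum < 1:
        raise ValueError("max_stratum must be >= 1")
    df = table.data[table.data["stratum"] <= max_stratum].reset_index(drop=True)
    return CountingProcessTable(df, table.clock, list(table.covariate_names))
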