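"""Non-parametric mean cumulative function (Nelson-Aalen) estimation.

The MCF is the expected cumulative number of events per participant
over time, estimated by the Nelson-Aalen estimator applied to the
recurrent-event counting process: a step function jumping
dN.(t) / Y.(t) at each observed event time, where dN.(t) counts events
at t across all subjects (ties contribute a single pooled jump) and
Y.(t) counts subjects still under observation at t-.  Unlike the
conditional risk sets of the PWP table, a subject stays in Y.(t)
through their followup_end however many events they have had.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataprep import SubjectEventHistory

__all__ = ["MCFCurve", "mcf_estimate", "mcf_plot_data"]


@dataclass
class MCFCurve:
    """One group's MCF step function with at-risk bookkeeping."""

    group: str
    data: pd.DataFrame  # columns: time, dN, at_risk, increment, mcf
    n_subjects: int
    followup_ends: np.ndarray = None  # sorted observation-end times

    def evaluate(self, times) -> np.ndarray:
        t = self.data["time"].to_numpy()
        m = np.concatenate([[0.0], self.data["mcf"].to_numpy()])
        return m[np.searchsorted(t, np.asarray(times, float), side="right")]

    def at_risk(self, times) -> np.ndarray:
        """Subjects still under observation at each time (Y(t))."""
        ends = self.followup_ends
        t = np.asarray(times, float)
        return len(ends) - np.searchsorted(ends, t, side="left")


def _one_group(histories: list[SubjectEventHistory], window_end: float, label: str) -> MCFCurve:
    if not histories:
        raise ValueError(f"empty group {label!r}")
    ends = np.array([min(h.followup_end, window_end) for h in histories])
    events = np.concatenate(
        [
            np.asarray([t for t in h.event_times if t <= min(h.followup_end, window_end)])
            for h in histories
        ]
        or [np.array([])]
    )
    times, dN = np.unique(events, return_counts=True)
    # Y(t): subjects under observation at t- (followup_end >= t)
    at_risk = (ends[None, :] >= times[:, None]).sum(axis=1) if len(times) else np.array([], int)
    keep = at_risk > 0  # J(t) guard: skip jump times with empty risk set
    times, dN, at_risk = times[keep], dN[keep], at_risk[keep]
    inc = dN / at_risk
    df = pd.DataFrame(
        {"time": times, "dN": dN, "at_risk": at_risk, "increment": inc, "mcf": np.cumsum(inc)}
    )
    return MCFCurve(
        group=label, data=df, n_subjects=len(histories), followup_ends=np.sort(ends)
    )


def mcf_estimate(
    histories: Iterable[SubjectEventHistory],
    window_end: float,
    group_by_arm: bool = True,
) -> dict[str, MCFCurve]:
    """Nelson-Aalen MCF per treatment group (or pooled).

    Returns a dict keyed by group label ("intervention"/"control", or
    "all""); each curve starts at 0 and is non-decreasing.
    """
    hs = [h.validate() for h in histories]
    if not hs:
        raise ValueError("empty population")
    if not group_by_arm:
        return {"all": _one_group(hs, window_end, "all")}
    out = {}
    for arm, label in ((1, "intervention"), (0, "control")):
        grp = [h for h in hs if h.arm == arm]
        if grp:
            out[label] = _one_group(grp, window_end, label)
    if not out:
        raise ValueError("no non-empty group")
    return out


def mcf_plot_data(
    curves: dict[str, MCFCurve], at_risk_times: Sequence[float] = ()
) -> dict[str, pd.DataFrame]:
    """Plot-ready step coordinates plus an at-risk table.

    Returns {"steps": long DataFrame(group, time, mcf) with duplicated
    x-coordinates forming the step path, "at_risk": DataFrame of subject
    counts still under observation at the requested round time points}.
    """
    if not curves:
        raise ValueError("no curves supplied")
    step_frames = []
    for label, c in curves.items():
        t = c.data["time"].to_numpy()
        m = c.data["mcf"].to_numpy()
        # horizontal-then-vertical step path starting at (0, 0)
        xs = np.concatenate([[0.0], np.repeat(t, 2)])
        ys = np.concatenate([[0.0, 0.0], np.repeat(m, 2)[:-1]])
        step_frames.append(pd.DataFrame({"group": label, "time": xs, "mcf": ys}))
    steps = pd.concat(step_frames, ignore_index=True)
    risk_rows = [
        {"group": label, "time": tp, "at_risk": int(c.at_risk([tp])[0])}
        for label, c in curves.items()
        for tp in at_risk_times
    ]
    at_risk = pd.DataFrame(risk_rows, columns=["group", "time", "at_risk"])
    return {"steps": steps, "at_risk": at_risk}
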