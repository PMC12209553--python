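"""Headline outputs: intensity ratios, diagnostics and advisories.

Global and event-specific intensity ratios (IR = exp of the arm
coefficient) with Wald 95% confidence intervals on the log scale,
event-dependence diagnostics (per-stratum Nelson-Aalen cumulative
hazards on the gap clock), rare-events advisories recommending Firth
penalisation, and the truncation / frailty-distribution sensitivity
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cox import ModelSpec, fit_cox
from .dataprep import (
    CountingProcessTable,
    compute_truncation_points,
    max_stratum_for_threshold,
    truncate_events,
)
from .frailty import fit_conditional_frailty

__all__ = [
    "EffectEstimate",
    "AdvisoryReport",
    "global_effect",
    "event_specific_effects",
    "event_dependence_diagnostic",
    "rare_events_check",
    "sensitivity_suite",
    "TRUNCATION_FRACTIONS",
]

# the five sensitivity truncation fractions of the population size
TRUNCATION_FRACTIONS = (0.05, 0.02, 0.01, 0.005, 0.0025)


@dataclass
class EffectEstimate:
    """One intensity-ratio estimate with its Wald interval."""

    label: str
    ir: float
    ci_lower: float
    ci_upper: float
    pvalue: float
    coef: float
    se: float
    n_at_risk: int = 0
    estimable: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "IR": self.ir,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.pvalue,
            "coef": self.coef,
            "se": self.se,
            "n_at_risk": self.n_at_risk,
            "estimable": self.estimable,
            "note": self.note,
        }


@dataclass
class AdvisoryReport:
    """Deterministic data-quality flags for rare events and truncation."""

    firth_recommended: bool
    n_subjects: int
    n_recurrent_subjects: int
    recurrent_proportion: float
    n_predictors: int
    epv_minimum_rule10: int
    epv_minimum_rule6: int
    small_risk_set_strata: list = field(default_factory=list)
    recommended_truncation: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)


def _wald_estimate(label, coef, se, n_at_risk=0, z=1.96) -> EffectEstimate:
    p = 2 * float(scipy.stats.norm.sf(abs(coef) / se)) if se > 0 else float("nan")
    with np.errstate(over="ignore"):
        return EffectEstimate(
            label=label,
            ir=float(np.exp(coef)),
            ci_lower=float(np.exp(coef - z * se)),
            ci_upper=float(np.exp(coef + z * se)),
            pvalue=p,
            coef=float(coef),
            se=float(se),
            n_at_risk=n_at_risk,
        )


def global_effect(fit, term: str = "arm") -> EffectEstimate:
    """Global intensity ratio for the treatment arm over the window.

    IR = exp(beta_arm) with the Wald 95% CI exp(beta +/- 1.96 SE); the
    robust (cluster sandwich) SE is used when the fit carries one.
    """
    if term not in fit.beta.index:
        raise ValueError(f"fit has no {term!r} coefficient")
    se = fit.se()[term]
    return _wald_estimate("global", fit.beta[term], se, n_at_risk=getattr(fit, "n_events", 0))


def event_specific_effects(
    table: CountingProcessTable, spec: ModelSpec
) -> list[EffectEstimate]:
    """Per-event-number intensity ratios from one joint interaction fit.

    The arm effect is stratum-specific (arm-by-stratum interaction)
    while all other covariates share a single coefficient across event
    numbers.  Strata with zero events in either arm are flagged
    non-estimable and reported, not silently dropped.
    """
    spec = spec.with_(interaction="arm-by-stratum")
    df = table.data
    strata = sorted(df["stratum"].unique())
    bad = {}
    for k in strata:
        sub = df[(df["stratum"] == k) & (df["status"] == 1)]
        for arm in (0, 1):
            if (sub["arm"] == arm).sum() == 0:
                bad[k] = f"no events in arm {arm}"
    spec = spec.with_(interaction_exclude=tuple(sorted(bad)))
    if spec.frailty != "none":
        fit = fit_conditional_frailty(table, spec)
    else:
        fit = fit_cox(table, spec)
    sizes = df.groupby("stratum").size()
    out = []
    for k in strata:
        name = f"arm:stratum{k}"
        if k in bad or name not in fit.beta.index:
            out.append(
                EffectEstimate(
                    label=f"event {k}",
                    ir=float("nan"),
                    ci_lower=float("nan"),
                    ci_upper=float("nan"),
                    pvalue=float("nan"),
                    coef=float("nan"),
                    se=float("nan"),
                    n_at_risk=int(sizes.get(k, 0)),
                    estimable=False,
                    note=bad.get(k, "term absent from fit"),
                )
            )
            continue
        est = _wald_estimate(
            f"event {k}", fit.beta[name], fit.se()[name], n_at_risk=int(sizes[k])
        )
        if abs(est.coef) > 10:  # monotone likelihood within the stratum
            est.estimable = False
            est.note = "quasi-separated stratum (consider Firth or truncation)"
        out.append(est)
    return out


def event_dependence_diagnostic(table: CountingProcessTable) -> dict[int, pd.DataFrame]:
    """Per-stratum Nelson-Aalen cumulative hazards on the gap clock.

    Curves that separate by event number indicate event dependence
    (event-specific baseline hazards), supporting stratification; curves
    that coincide support the common-baseline (standard frailty / AG)
    alternative.  Returns plot-ready step data per stratum.
    """
    df = table.data
    out = {}
    for k, grp in df.groupby("stratum"):
        gap = (grp["stop"] - grp["start"]).to_numpy()
        status = grp["status"].to_numpy()
        etimes, dN = np.unique(gap[status == 1], return_counts=True)
        if not len(etimes):
            out[int(k)] = pd.DataFrame(columns=["time", "at_risk", "dN", "cumhaz"])
            continue
        at_risk = (gap[None, :] >= etimes[:, None]).sum(axis=1)
        jumps = dN / at_risk
        out[int(k)] = pd.DataFrame(
            {"time": etimes, "at_risk": at_risk, "dN": dN, "cumhaz": np.cumsum(jumps)}
        )
    return out


def rare_events_check(table: CountingProcessTable, n_predictors: int) -> AdvisoryReport:
    """Advise on a rare-events (Firth) adjustment and sparse strata.

    Firth penalisation is recommended when fewer than 1% of participants
    have recurrent (>= 2) events, or when the count of such participants
    falls below 20 per predictor.  The classical events-per-variable
    minima (10 and 6 per predictor) are reported for context, and the
    five standard truncation fractions are translated into recommended
    event caps for this table.
    """
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    df = table.data
    n_subjects = df["subject_id"].nunique()
    events_per_subject = df[df["status"] == 1].groupby("subject_id").size()
    n_recurrent = int((events_per_subject >= 2).sum())
    prop = n_recurrent / n_subjects
    flag = prop < 0.01 or n_recurrent < 20 * n_predictors
    thresholds = compute_truncation_points(n_subjects, TRUNCATION_FRACTIONS)
    sizes = df.groupby("stratum").size()
    small = sizes[sizes <= thresholds[-1]].index.tolist()
    rec = {
        frac: {"threshold": thr, "max_stratum": max_stratum_for_threshold(table, thr)}
        for frac, thr in zip(TRUNCATION_FRACTIONS, thresholds)
    }
    messages = []
    if flag:
        messages.append(
            f"{n_recurrent} participants ({100 * prop:.2f}%) have recurrent events; "
            f"below 1% of the population or 20 per predictor "
            f"({20 * n_predictors}) — consider Firth's penalised likelihood"
        )
    if small:
        messages.append(
            f"strata {small} have risk sets at or below {thresholds[-1]} participants"
        )
    return AdvisoryReport(
        firth_recommended=bool(flag),
        n_subjects=int(n_subjects),
        n_recurrent_subjects=n_recurrent,
        recurrent_proportion=float(prop),
        n_predictors=int(n_predictors),
        epv_minimum_rule10=10 * n_predictors,
        epv_minimum_rule6=6 * n_predictors,
        small_risk_set_strata=[int(s) for s in small],
        recommended_truncation=rec,
        messages=messages,
    )


def sensitivity_suite(
    table: CountingProcessTable,
    truncation_fractions: Sequence[float] = TRUNCATION_FRACTIONS,
    frailty_distributions: Sequence[str] = ("gamma", "lognormal"),
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Global-effect fits across truncation points and frailty choices.

    One labelled row per (truncation fraction, frailty distribution)
    variant; individual variant failures are recorded in the ``error``
    column and the suite continues.
    """
    if spec is None:
        spec = ModelSpec(clock=table.clock, stratified=True, frailty="gamma")
    n_subjects = table.n_subjects
    thresholds = compute_truncation_points(n_subjects, truncation_fractions)
    rows = []
    for frac, thr in zip(truncation_fractions, thresholds):
        kmax = max_stratum_for_threshold(table, thr)
        sub = truncate_events(table, kmax)
        for dist in frailty_distributions:
            label = f"truncate>{thr} ({100 * frac:g}%), {dist}"
            try:
                fit = fit_conditional_frailty(sub, spec.with_(frailty=dist))
                est = global_effect(fit)
                rows.append(
                    {
                        "label": label,
                        "fraction": frac,
                        "threshold": thr,
                        "max_stratum": kmax,
                        "frailty": dist,
                        "IR": est.ir,
                        "ci_lower": est.ci_lower,
                        "ci_upper": est.ci_upper,
                        "p": est.pvalue,
                        "theta": fit.theta,
                        "error": "",
                    }
                )
            except Exception as exc:  # noqa: BLE001 — per-variant failure is data
                rows.append(
                    {
                        "label": label,
                        "fraction": frac,
                        "threshold": thr,
                        "max_stratum": kmax,
                        "frailty": dist,
                        "IR": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "p": np.nan,
                        "theta": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
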