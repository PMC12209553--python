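"""Stratified counting-process Cox engine.

Maximises the Cox partial likelihood on (start, stop] risk-interval data
with event-number strata, Efron or Breslow tie handling, optional Firth
penalisation for rare events / monotone likelihood, a cluster-level
sandwich (robust) covariance, and the Breslow baseline cumulative
hazard.  The model family is selected by :class:`ModelSpec`:

* stratified off, total clock  -> Andersen-Gill (AG) intensity
* stratified on,  total clock  -> PWP total-time
* stratified on,  gap clock    -> PWP gap-time
* stratified on,  gap clock, + frailty -> conditional frailty model
  (fitted by :mod:`cfrail.frailty` on top of this engine)

Risk-set sums at each event time are computed as differences of
cumulative sums over stop-sorted and start-sorted rows (delayed entry
handled exactly), so one likelihood/gradient/Hessian evaluation costs
O(n log n + n p^2) per stratum regardless of the number of distinct
event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .dataprep import CountingProcessTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "BaselineHazard",
    "partial_loglik",
    "fit_cox",
    "fit_firth",
    "robust_covariance",
    "baseline_cumhaz",
]


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one member of the Cox intensity-model family.

    Attributes
    ----------
    clock : {"gap", "total"}
        Risk-interval clock; must match the counting-process table.
    stratified : bool
        Event-number-specific baseline hazards (restricted risk sets).
    frailty : {"none", "gamma", "lognormal"}
        Cluster-level shared frailty distribution.
    firth : bool
        Firth (Jeffreys-prior) penalisation of the partial likelihood.
    ties : {"efron", "breslow"}
        Tied-event correction; the two coincide exactly on tie-free data.
    robust_cluster : bool
        Compute the cluster-level sandwich covariance after fitting.
    covariates : sequence of str
        Baseline covariate columns to include beside the arm term.
    interaction : {"none", "arm-by-stratum"}
        Stratum-specific arm effects (event-specific intensity ratios).
    """

    clock: Literal["gap", "total"] = "gap"
    stratified: bool = True
    frailty: Literal["none", "gamma", "lognormal"] = "none"
    firth: bool = False
    ties: Literal["efron", "breslow"] = "efron"
    robust_cluster: bool = False
    covariates: Sequence[str] = ()
    interaction: Literal["none", "arm-by-stratum"] = "none"
    interaction_exclude: Sequence[int] = ()  # strata without an arm term
    include_arm: bool = True

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


class CoxData:
    """Per-stratum design matrices and precomputed risk-set indices."""

    def __init__(self, table: CountingProcessTable, spec: ModelSpec,
                 extra_columns: Optional[pd.DataFrame] = None):
        df = table.data
        if spec.clock != table.clock:
            raise ValueError(
                f"spec clock {spec.clock!r} does not match table clock {table.clock!r}"
            )
        cols: list[str] = []
        X_parts: list[np.ndarray] = []
        if spec.interaction == "arm-by-stratum":
            if not spec.stratified:
                raise ValueError("arm-by-stratum interaction requires stratification")
            for k in sorted(df["stratum"].unique()):
                if k in spec.interaction_exclude:
                    continue
                cols.append(f"arm:stratum{k}")
                X_parts.append(
                    df["arm"].to_numpy(float) * (df["stratum"] == k).to_numpy(float)
                )
        elif spec.include_arm:
            cols.append("arm")
            X_parts.append(df["arm"].to_numpy(float))
        for name in spec.covariates:
            if name not in df:
                raise KeyError(f"covariate {name!r} not in table")
            cols.append(name)
            X_parts.append(df[name].to_numpy(float))
        if extra_columns is not None:
            for name in extra_columns.columns:
                cols.append(name)
                X_parts.append(extra_columns[name].to_numpy(float))
        if not cols:
            raise ValueError("model has no covariates")
        X = np.column_stack(X_parts)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values")
        self.columns = cols
        self.X = X
        self.n, self.p = X.shape
        self.status = df["status"].to_numpy(int)
        self.start = df["start"].to_numpy(float)
        self.stop = df["stop"].to_numpy(float)
        self.subject_id = df["subject_id"].to_numpy()
        self.cluster_id = df["cluster_id"].to_numpy()
        self.strata = (
            df["stratum"].to_numpy() if spec.stratified else np.ones(self.n, int)
        )
        self.spec = spec
        self._build_risk_sets()

    def _build_risk_sets(self) -> None:
        self.blocks = []
        for k in np.unique(self.strata):
            idx = np.flatnonzero(self.strata == k)
            start, stop, status = self.start[idx], self.stop[idx], self.status[idx]
            ev = status == 1
            etimes, ev_tpos_all = np.unique(stop[ev], return_inverse=True)
            blk = dict(k=k, idx=idx, etimes=etimes, n=len(idx))
            if etimes.size:
                d = np.bincount(ev_tpos_all).astype(float)
                ss_order = np.argsort(stop, kind="stable")
                st_order = np.argsort(start, kind="stable")
                blk.update(
                    d=d,
                    ev=ev,
                    ev_tpos=ev_tpos_all,
                    ss_order=ss_order,
                    st_order=st_order,
                    # counts of stops/starts strictly below each event time
                    pos_stop=np.searchsorted(stop[ss_order], etimes, side="left"),
                    pos_start=np.searchsorted(start[st_order], etimes, side="left"),
                    # structural at-risk counts, independent of beta
                    n_risk=(
                        np.searchsorted(start[st_order], etimes, side="left")
                        - np.searchsorted(stop[ss_order], etimes, side="left")
                    ),
                    # number of event times inside (start_r, stop_r] per row
                    cnt_hi=np.searchsorted(etimes, stop, side="right"),
                    cnt_lo=np.searchsorted(etimes, start, side="right"),
                    tidx=np.repeat(np.arange(etimes.size), d.astype(int)),
                    frac=np.concatenate(
                        [np.arange(int(dt)) / dt for dt in d]
                    ),
                )
            self.blocks.append(blk)
        const = 0.0
        for b in self.blocks:
            if b["etimes"].size:
                const += float(np.sum(b["d"] * np.log(b["d"])) - np.sum(b["d"]))
        self.full_loglik_const = const
        self.n_events = int(self.status.sum())

    # -- risk-set sums ---------------------------------------------------
    @staticmethod
    def _prefix(values: np.ndarray) -> np.ndarray:
        """prefix[i] = sum(values[:i]) with a leading zero row."""
        if values.ndim == 1:
            return np.concatenate([[0.0], np.cumsum(values)])
        return np.vstack([np.zeros((1, values.shape[1])), np.cumsum(values, axis=0)])

    @staticmethod
    def _suffix(values: np.ndarray) -> np.ndarray:
        """suffix[i] = sum(values[i:]) with a trailing zero row."""
        if values.ndim == 1:
            out = np.zeros(len(values) + 1)
            out[:-1] = np.cumsum(values[::-1])[::-1]
            return out
        out = np.zeros((values.shape[0] + 1, values.shape[1]))
        out[:-1] = np.cumsum(values[::-1], axis=0)[::-1]
        return out

    def _risk_sums(self, b, w, wX=None):
        """S0 (and S1) at each event time via sorted suffix sums.

        S0(t) = sum_{stop >= t} w - sum_{start >= t} w: rows that have
        entered (start < t) and not yet left (stop >= t).  Suffix sums
        avoid cancellation against the stratum total; under the gap
        clock the entry term is identically zero.  Any residually
        non-positive S0 (extreme linear predictors under the total
        clock) is recomputed exactly from the row masks.
        """
        R_stop = self._suffix(w[b["ss_order"]])
        R_start = self._suffix(w[b["st_order"]])
        S0 = R_stop[b["pos_stop"]] - R_start[b["pos_start"]]
        bad = np.flatnonzero(S0 <= 0)
        if bad.size:
            if np.any(b["n_risk"][bad] == 0):
                t_bad = b["etimes"][bad[np.argmax(b["n_risk"][bad] == 0)]]
                raise ValueError(
                    f"empty risk set in stratum {b['k']} at time {t_bad}"
                )
            idx = b["idx"]
            start, stop = self.start[idx], self.stop[idx]
            for j in bad:
                t = b["etimes"][j]
                S0[j] = w[(start < t) & (t <= stop)].sum()
        S1 = None
        if wX is not None:
            RX_stop = self._suffix(wX[b["ss_order"]])
            RX_start = self._suffix(wX[b["st_order"]])
            S1 = RX_stop[b["pos_stop"]] - RX_start[b["pos_start"]]
            if bad.size:
                idx = b["idx"]
                start, stop = self.start[idx], self.stop[idx]
                for j in bad:
                    t = b["etimes"][j]
                    S1[j] = wX[(start < t) & (t <= stop)].sum(axis=0)
        return S0, S1

    def _interval_sum(self, b, per_time: np.ndarray) -> np.ndarray:
        """Per-row sums of a per-event-time quantity over (start, stop]."""
        F = self._prefix(per_time)
        return F[b["cnt_hi"]] - F[b["cnt_lo"]]

    # -- likelihood ------------------------------------------------------
    def loglik(self, beta, offset=None, ties=None, want_hess=True):
        """Partial log-likelihood, gradient and Hessian at ``beta``.

        ``offset`` is an optional per-row linear-predictor offset (used
        for fixed frailty terms).  Returns ``(value, grad, hess)``;
        ``hess`` is ``None`` when ``want_hess`` is false.
        """
        ties = ties or self.spec.ties
        beta = np.asarray(beta, float)
        eta = self.X @ beta
        if offset is not None:
            eta = eta + offset
        ll = 0.0
        grad = np.zeros(self.p)
        hess = np.zeros((self.p, self.p)) if want_hess else None
        for b in self.blocks:
            if not b["etimes"].size:
                continue
            idx = b["idx"]
            Xs = self.X[idx]
            eta_s = eta[idx]
            shift = eta_s.max()
            w = np.exp(eta_s - shift)
            wX = w[:, None] * Xs
            S0, S1 = self._risk_sums(b, w, wX)
            if np.any(S0 <= 0):
                # exp(eta) underflow at an extreme candidate beta: signal
                # -inf so line searches back off rather than aborting
                return -np.inf, None, None
            ev, d = b["ev"], b["d"]
            ll += float(eta_s[ev].sum())
            if ties == "breslow":
                ll -= float(np.sum(d * (np.log(S0) + shift)))
                c = self._interval_sum(b, d / S0)
                grad += Xs[ev].sum(axis=0) - Xs.T @ (w * c)
                if want_hess:
                    U = S1 / S0[:, None]
                    hess -= Xs.T @ (Xs * (w * c)[:, None]) - (U * d[:, None]).T @ U
            else:  # efron
                s0D = np.bincount(b["ev_tpos"], weights=w[ev], minlength=len(S0))
                s1D = np.zeros_like(S1)
                np.add.at(s1D, b["ev_tpos"], wX[ev])
                tidx, frac = b["tidx"], b["frac"]
                denom = S0[tidx] - frac * s0D[tidx]
                ll -= float(np.sum(np.log(denom) + shift))
                inv = 1.0 / denom
                a = np.bincount(tidx, weights=inv, minlength=len(S0))
                bcoef = np.bincount(tidx, weights=frac * inv, minlength=len(S0))
                c = self._interval_sum(b, a)
                c[ev] -= bcoef[b["ev_tpos"]]
                grad += Xs[ev].sum(axis=0) - Xs.T @ (w * c)
                if want_hess:
                    V = (S1[tidx] - frac[:, None] * s1D[tidx]) * inv[:, None]
                    hess -= Xs.T @ (Xs * (w * c)[:, None]) - V.T @ V
        return ll, grad, hess

    def full_loglik(self, beta, offset=None) -> float:
        """Breslow-profiled full log-likelihood (partial + jump terms).

        Differs from the Breslow partial log-likelihood by a constant of
        the data only, so it is comparable across nested models on the
        same table — including the integrated frailty likelihood.
        """
        ll, _, _ = self.loglik(beta, offset=offset, ties="breslow", want_hess=False)
        return ll + self.full_loglik_const

    def score_residuals(self, beta, offset=None, ties=None) -> np.ndarray:
        """Per-row score residuals; rows sum exactly to the score vector.

        Efron ties are handled through the pseudo-risk-set decomposition
        so the residuals stay consistent with the Efron score.
        """
        ties = ties or self.spec.ties
        beta = np.asarray(beta, float)
        eta = self.X @ beta
        if offset is not None:
            eta = eta + offset
        resid = np.zeros((self.n, self.p))
        for b in self.blocks:
            if not b["etimes"].size:
                continue
            idx = b["idx"]
            Xs = self.X[idx]
            eta_s = eta[idx]
            shift = eta_s.max()
            w = np.exp(eta_s - shift)
            wX = w[:, None] * Xs
            S0, S1 = self._risk_sums(b, w, wX)
            ev, d = b["ev"], b["d"]
            T = len(S0)
            if ties == "breslow":
                U = S1 / S0[:, None]
                c = self._interval_sum(b, d / S0)
                ubar = U
                P = U * (d / S0)[:, None]
                Q = np.zeros((T, self.p))
            else:
                s0D = np.bincount(b["ev_tpos"], weights=w[ev], minlength=T)
                s1D = np.zeros_like(S1)
                np.add.at(s1D, b["ev_tpos"], wX[ev])
                tidx, frac = b["tidx"], b["frac"]
                denom = S0[tidx] - frac * s0D[tidx]
                inv = 1.0 / denom
                a = np.bincount(tidx, weights=inv, minlength=T)
                bcoef = np.bincount(tidx, weights=frac * inv, minlength=T)
                c = self._interval_sum(b, a)
                c[ev] -= bcoef[b["ev_tpos"]]
                V = (S1[tidx] - frac[:, None] * s1D[tidx]) * inv[:, None]
                ubar = np.zeros((T, self.p))
                np.add.at(ubar, tidx, V)
                ubar /= d[:, None]
                P = np.zeros((T, self.p))
                np.add.at(P, tidx, V * inv[:, None])
                Q = np.zeros((T, self.p))
                np.add.at(Q, tidx, V * (frac * inv)[:, None])
            r = np.zeros((len(idx), self.p))
            r[ev] = Xs[ev] - ubar[b["ev_tpos"]]
            MTP = self._interval_sum(b, P)
            ETQ = np.zeros((len(idx), self.p))
            ETQ[ev] = Q[b["ev_tpos"]]
            comp = Xs * (w * c)[:, None] - w[:, None] * (MTP - ETQ)
            resid[idx] = r - comp
        return resid

    def breslow_jumps(self, beta, offset=None) -> dict:
        """Breslow baseline-hazard jumps d_t / S0(t) per stratum."""
        beta = np.asarray(beta, float)
        eta = self.X @ beta
        if offset is not None:
            eta = eta + offset
        out = {}
        for b in self.blocks:
            if not b["etimes"].size:
                out[b["k"]] = (np.array([]), np.array([]))
                continue
            idx = b["idx"]
            shift = eta[idx].max()
            w = np.exp(eta[idx] - shift)  # rescaled to avoid overflow
            S0, _ = self._risk_sums(b, w)
            out[b["k"]] = (b["etimes"], b["d"] / S0 * np.exp(-shift))
        return out

    def cumhaz_per_row(self, jumps: dict) -> np.ndarray:
        """Baseline cumulative hazard accrued over each row's interval."""
        out = np.zeros(self.n)
        for b in self.blocks:
            etimes, jmp = jumps[b["k"]]
            if not len(etimes):
                continue
            idx = b["idx"]
            cum = np.concatenate([[0.0], np.cumsum(jmp)])
            out[idx] = cum[b["cnt_hi"]] - cum[b["cnt_lo"]]
        return out


@dataclass
class FitResult:
    """Maximum partial-likelihood fit of one model in the family."""

    beta: pd.Series
    covariance: pd.DataFrame
    loglik_null: float
    loglik_final: float
    loglik_full: float
    iterations: int
    converged: bool
    separation: bool
    score: np.ndarray
    information: np.ndarray
    n_events: int
    spec: ModelSpec
    robust_covariance: Optional[pd.DataFrame] = None
    firth: bool = False
    _data: CoxData = field(default=None, repr=False)
    _offset: Optional[np.ndarray] = field(default=None, repr=False)

    def se(self, robust: bool | None = None) -> pd.Series:
        """Standard errors; cluster-sandwich values when available."""
        if robust is None:
            robust = self.robust_covariance is not None
        cov = self.robust_covariance if robust else self.covariance
        if cov is None:
            raise ValueError("robust covariance not computed")
        return pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=self.beta.index)

    def summary(self) -> pd.DataFrame:
        se = self.se(robust=False)
        rows = {"coef": self.beta, "exp(coef)": np.exp(self.beta), "se": se}
        use = se
        if self.robust_covariance is not None:
            rows["robust_se"] = use = self.se(robust=True)
        z = self.beta / use
        rows["z"] = z
        rows["p"] = 2 * scipy.stats.norm.sf(np.abs(z))
        rows["ir_lower95"] = np.exp(self.beta - 1.96 * use)
        rows["ir_upper95"] = np.exp(self.beta + 1.96 * use)
        return pd.DataFrame(rows)


@dataclass
class BaselineHazard:
    """Per-stratum Breslow cumulative baseline hazard step functions."""

    curves: dict  # stratum -> DataFrame(time, jump, cumhaz)

    def evaluate(self, stratum, times) -> np.ndarray:
        df = self.curves[stratum]
        t = df["time"].to_numpy()
        c = np.concatenate([[0.0], df["cumhaz"].to_numpy()])
        return c[np.searchsorted(t, np.asarray(times, float), side="right")]


def partial_loglik(beta, table: CountingProcessTable, spec: ModelSpec, offset=None):
    """Partial log-likelihood with gradient and Hessian (public wrapper)."""
    return CoxData(table, spec).loglik(beta, offset=offset)


def _check_rank(data: CoxData) -> None:
    info0 = -data.loglik(np.zeros(data.p))[2]
    dd = np.sqrt(np.clip(np.diag(info0), 1e-300, None))
    corr = info0 / np.outer(dd, dd)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] < 1e-8:
        v = np.abs(eigvecs[:, 0])
        bad = [data.columns[j] for j in np.flatnonzero(v > 0.3 * v.max())]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _newton(
    data: CoxData,
    offset=None,
    beta0=None,
    max_iter: int = 50,
    gtol: float = 1e-6,
    lltol: float = 1e-9,
    separation_bound: float = 10.0,
):
    beta = np.zeros(data.p) if beta0 is None else np.asarray(beta0, float).copy()
    ll, g, H = data.loglik(beta, offset=offset)
    ll_null = data.loglik(np.zeros(data.p), offset=offset, want_hess=False)[0]
    converged = separation = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, g, rcond=None)[0]
        new_beta = beta + step
        new = None
        for _ in range(25):  # step halving
            new = data.loglik(new_beta, offset=offset)
            if np.isfinite(new[0]) and new[0] >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2
        if not np.isfinite(new[0]):
            break
        rel = abs(new[0] - ll) / max(1.0, abs(new[0]))
        beta, (ll, g, H) = new_beta, new
        if np.max(np.abs(g)) < gtol and rel < lltol:
            converged = True
            break
        big = np.abs(beta) > separation_bound
        if np.any(big) and np.any(np.sign(g[big]) == np.sign(beta[big])):
            separation = True  # monotone likelihood: optimum at infinity
            break
    return beta, ll, ll_null, g, H, it, converged, separation


def fit_cox(
    table: CountingProcessTable,
    spec: ModelSpec,
    offset=None,
    beta0=None,
    max_iter: int = 50,
) -> FitResult:
    """Newton-Raphson maximisation of the (stratified) partial likelihood.

    Monotone likelihood (separation) — a coefficient walking past ±10
    with the score still pushing outward — is detected and flagged
    rather than iterated to a pseudo-optimum; Firth penalisation
    (:func:`fit_firth`) is the recommended remedy.
    """
    if spec.firth:
        return fit_firth(table, spec, offset=offset, max_iter=max_iter)
    data = CoxData(table, spec)
    if data.n_events == 0:
        raise ValueError("no events in table")
    _check_rank(data)
    beta, ll, ll_null, g, H, it, converged, separation = _newton(
        data, offset=offset, beta0=beta0, max_iter=max_iter
    )
    info = -H
    fit = FitResult(
        beta=pd.Series(beta, index=data.columns),
        covariance=pd.DataFrame(
            _safe_inverse(info), index=data.columns, columns=data.columns
        ),
        loglik_null=ll_null,
        loglik_final=ll,
        loglik_full=data.full_loglik(beta, offset=offset),
        iterations=it,
        converged=converged,
        separation=separation,
        score=g,
        information=info,
        n_events=data.n_events,
        spec=spec,
        _data=data,
        _offset=None if offset is None else np.asarray(offset, float),
    )
    if spec.robust_cluster:
        fit.robust_covariance = robust_covariance(fit)
    return fit


def _safe_inverse(info: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def _penalised(data: CoxData, beta, offset=None):
    """Firth-penalised value and modified score.

    Penalty = 0.5 log det I(beta); its gradient is obtained by central
    finite differences of the log-determinant (2p Hessian evaluations),
    avoiding third-derivative tensors.  Returns None when the
    information matrix is not positive definite at ``beta``.
    """
    ll, g, H = data.loglik(beta, offset=offset)
    if not np.isfinite(ll):
        return None
    sign, logdet = np.linalg.slogdet(-H)
    if sign <= 0:
        return None
    pen_grad = np.zeros(data.p)
    for j in range(data.p):
        h = 1e-5 * max(1.0, abs(beta[j]))
        for s in (+1, -1):
            bj = beta.copy()
            bj[j] += s * h
            _, _, Hj = data.loglik(bj, offset=offset)
            sj, ldj = np.linalg.slogdet(-Hj)
            if sj <= 0:
                return None
            pen_grad[j] += s * ldj / (2 * h)
    return ll + 0.5 * logdet, g + 0.5 * pen_grad, H


def fit_firth(
    table: CountingProcessTable,
    spec: ModelSpec,
    offset=None,
    max_iter: int = 50,
    gtol: float = 1e-6,
) -> FitResult:
    """Maximise the Firth-penalised partial likelihood.

    The objective log Lp(beta) + 0.5 log det I(beta) — the Jeffreys
    invariant-prior penalty — keeps the estimate finite under monotone
    likelihood and reduces small-sample bias when events are rare.
    """
    data = CoxData(table, spec)
    if data.n_events == 0:
        raise ValueError("no events in table")
    _check_rank(data)
    beta = np.zeros(data.p)
    state = _penalised(data, beta, offset)
    if state is None:
        raise np.linalg.LinAlgError("information matrix singular at beta = 0")
    pll, gstar, H = state
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(-H, gstar)
        new_beta = beta + step
        new = None
        for _ in range(25):
            new = _penalised(data, new_beta, offset)
            if new is not None and new[0] >= pll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2
        if new is None:
            raise np.linalg.LinAlgError(
                "information matrix singular at every candidate step"
            )
        rel = abs(new[0] - pll) / max(1.0, abs(new[0]))
        beta, (pll, gstar, H) = new_beta, new
        if np.max(np.abs(gstar)) < gtol and rel < 1e-9:
            converged = True
            break
    info = -H
    fit = FitResult(
        beta=pd.Series(beta, index=data.columns),
        covariance=pd.DataFrame(
            _safe_inverse(info), index=data.columns, columns=data.columns
        ),
        loglik_null=data.loglik(np.zeros(data.p), offset=offset, want_hess=False)[0],
        loglik_final=data.loglik(beta, offset=offset, want_hess=False)[0],
        loglik_full=data.full_loglik(beta, offset=offset),
        iterations=it,
        converged=converged,
        separation=False,
        score=gstar,
        information=info,
        n_events=data.n_events,
        spec=spec,
        firth=True,
        _data=data,
        _offset=None if offset is None else np.asarray(offset, float),
    )
    if spec.robust_cluster:
        fit.robust_covariance = robust_covariance(fit)
    return fit


def robust_covariance(fit: FitResult, table=None, cluster_ids=None) -> pd.DataFrame:
    """Cluster-level sandwich covariance I^-1 B I^-1.

    B aggregates score residuals within cluster; with one subject per
    cluster this reduces to the subject-grouped sandwich.
    """
    data = fit._data
    if cluster_ids is None:
        cluster_ids = data.cluster_id
    cluster_ids = np.asarray(cluster_ids)
    if len(pd.unique(cluster_ids)) < 2:
        raise ValueError("robust covariance requires at least 2 clusters")
    resid = data.score_residuals(fit.beta.to_numpy(), offset=fit._offset)
    grouped = pd.DataFrame(resid).groupby(pd.Series(cluster_ids)).sum().to_numpy()
    B = grouped.T @ grouped
    Iinv = _safe_inverse(fit.information)
    return pd.DataFrame(Iinv @ B @ Iinv, index=fit.beta.index, columns=fit.beta.index)


def baseline_cumhaz(fit: FitResult, table=None) -> BaselineHazard:
    """Breslow-type baseline cumulative hazard per stratum.

    Jump at each event time t: (events at t) / sum_{risk set} exp(beta'Z).
    At beta = 0 in a single stratum this reduces to the Nelson-Aalen
    estimator; the curves are non-decreasing by construction.
    """
    data = fit._data
    jumps = data.breslow_jumps(fit.beta.to_numpy(), offset=fit._offset)
    curves = {
        k: pd.DataFrame({"time": t, "jump": j, "cumhaz": np.cumsum(j)})
        for k, (t, j) in jumps.items()
    }
    return BaselineHazard(curves)
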