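"""Partial-likelihood engine: oracles, derivatives, model nesting."""

import numpy as np
import pandas as pd
import pytest

from cfrail.cox import (
    CoxData,
    ModelSpec,
    baseline_cumhaz,
    fit_cox,
    fit_firth,
    partial_loglik,
    robust_covariance,
)
from cfrail.dataprep import CountingProcessTable, build_counting_process
from cfrail.simulate import SimulationConfig, simulate_trial
from conftest import random_histories


def brute_force_loglik(data: CoxData, beta):
    """Naive row-by-row risk-set enumeration (Breslow), with gradient."""
    beta = np.asarray(beta, float)
    eta = data.X @ beta
    ll = 0.0
    grad = np.zeros(data.p)
    for b in data.blocks:
        idx = b["idx"]
        for i in idx[data.status[idx] == 1]:
            t = data.stop[i]
            rs = [j for j in idx if data.start[j] < t <= data.stop[j]]
            w = np.exp(eta[rs])
            ll += eta[i] - np.log(w.sum())
            grad += data.X[i] - (w[:, None] * data.X[rs]).sum(0) / w.sum()
    return ll, grad


def make_table(rows, clock="gap", covs=()):
    df = pd.DataFrame(
        rows,
        columns=["subject_id", "cluster_id", "stratum", "start", "stop", "status", "arm"]
        + list(covs),
    )
    return CountingProcessTable(df, clock, list(covs))


class TestPartialLoglik:
    def test_two_subject_closed_form(self, separation_table):
        value, grad, hess = partial_loglik([0.0], separation_table, ModelSpec(ties="breslow"))
        assert value == pytest.approx(-np.log(2))
        # closed form: l(b) = b - log(1 + e^b)
        for b in (-1.0, 0.5, 2.0):
            value, *_ = partial_loglik([b], separation_table, ModelSpec(ties="breslow"))
            assert value == pytest.approx(b - np.log(1 + np.exp(b)))

    def test_null_value_is_log_risk_set_sizes(self, rng):
        """At beta = 0 on tie-free data, ll = -sum(log |risk set|)."""
        histories = random_histories(rng, n_subjects=10)
        table = build_counting_process(histories, 122.0, "gap")
        data = CoxData(table, ModelSpec(covariates=("age",), ties="breslow"))
        expected = 0.0
        for b in data.blocks:
            idx = b["idx"]
            for i in idx[data.status[idx] == 1]:
                t = data.stop[i]
                expected -= np.log(
                    sum(1 for j in idx if data.start[j] < t <= data.stop[j])
                )
        value, *_ = data.loglik(np.zeros(data.p))
        assert value == pytest.approx(expected)

    @pytest.mark.parametrize("clock", ["gap", "total"])
    def test_matches_brute_force_enumeration(self, clock, rng):
        histories = random_histories(rng, n_subjects=10)
        table = build_counting_process(histories, 122.0, clock)
        data = CoxData(table, ModelSpec(clock=clock, covariates=("age",), ties="breslow"))
        beta = np.array([0.4, -0.02])
        value, grad, _ = data.loglik(beta)
        bll, bgrad = brute_force_loglik(data, beta)
        assert value == pytest.approx(bll)
        assert grad == pytest.approx(bgrad)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_gradient_hessian_match_finite_differences(self, ties):
        """Analytic derivatives agree with central differences to 1e-6."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            histories = random_histories(rng, n_subjects=8)
            table = build_counting_process(histories, 122.0, "gap")
            if table.n_events == 0:
                continue
            data = CoxData(table, ModelSpec(covariates=("age",), ties=ties))
            beta = rng.normal(0, 0.3, data.p)
            _, grad, hess = data.loglik(beta)
            eps = 1e-5
            for j in range(data.p):
                bp, bm = beta.copy(), beta.copy()
                bp[j] += eps
                bm[j] -= eps
                fp = data.loglik(bp, want_hess=False)[0]
                fm = data.loglik(bm, want_hess=False)[0]
                assert grad[j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5, abs=1e-7)
                gp = data.loglik(bp)[1]
                gm = data.loglik(bm)[1]
                assert hess[:, j] == pytest.approx((gp - gm) / (2 * eps), rel=1e-4, abs=1e-6)

    def test_efron_equals_breslow_on_tie_free_data(self, rng):
        histories = random_histories(rng, n_subjects=10)
        table = build_counting_process(histories, 122.0, "gap")
        data = CoxData(table, ModelSpec(covariates=("age",)))
        beta = np.array([0.2, 0.01])
        le = data.loglik(beta, ties="efron")
        lb = data.loglik(beta, ties="breslow")
        assert le[0] == pytest.approx(lb[0])
        assert le[1] == pytest.approx(lb[1])
        assert le[2] == pytest.approx(lb[2])

    def test_empty_risk_set_diagnostic_names_stratum_and_time(self):
        # a stratum-2 event before any subject enters it (total clock)
        rows = [
            ("a", "c", 1, 0.0, 5.0, 1, 1),
            ("a", "c", 2, 5.0, 9.0, 1, 1),
            ("b", "c", 1, 0.0, 20.0, 0, 0),
        ]
        table = make_table(rows, clock="total")
        data = CoxData(table, ModelSpec(clock="total"))
        # artificially break the risk set: zero-length event interval
        data.start[1] = 9.9
        data.stop[1] = 9.9
        data._build_risk_sets()
        with pytest.raises(ValueError, match="stratum"):
            data.loglik([0.0])


class TestFitCox:
    def test_monotone_likelihood_flagged(self, separation_table):
        fit = fit_cox(separation_table, ModelSpec(ties="breslow"))
        assert fit.separation and not fit.converged

    def test_grid_search_oracle_small_table(self):
        rows = [
            ("a", "c", 1, 0.0, 3.0, 1, 1),
            ("b", "c", 1, 0.0, 5.0, 1, 0),
            ("c", "c", 1, 0.0, 7.0, 1, 1),
            ("d", "c", 1, 0.0, 9.0, 1, 0),
            ("e", "c", 1, 0.0, 11.0, 1, 1),
            ("f", "c", 1, 0.0, 13.0, 0, 0),
        ]
        table = make_table(rows)
        spec = ModelSpec(ties="breslow")
        fit = fit_cox(table, spec)
        data = CoxData(table, spec)
        grid = np.arange(-5, 5, 1e-4)
        values = [data.loglik([b], want_hess=False)[0] for b in grid]
        assert fit.beta.iloc[0] == pytest.approx(grid[int(np.argmax(values))], abs=2e-4)

    def test_null_effect_recovered_on_simulated_data(self):
        cfg = SimulationConfig(
            n_clusters=40, subjects_per_cluster=25, theta=0.0, arm_log_ir=0.0,
            include_covariates=False, dropout_prob=0.0, seed=9,
        )
        histories, _ = simulate_trial(cfg)
        table = build_counting_process(histories, cfg.window, "gap")
        fit = fit_cox(table, ModelSpec())
        assert abs(fit.beta["arm"]) < 3 * fit.se(robust=False)["arm"]
        assert abs(fit.beta["arm"]) < 0.1

    def test_time_scaling_leaves_estimate_unchanged(self, small_trial):
        *_, table = small_trial
        spec = ModelSpec(covariates=("age",))
        fit1 = fit_cox(table, spec)
        scaled = CountingProcessTable(
            table.data.assign(start=table.data["start"] * 3.7, stop=table.data["stop"] * 3.7),
            table.clock,
            table.covariate_names,
        )
        fit2 = fit_cox(scaled, spec)
        assert fit1.beta.to_numpy() == pytest.approx(fit2.beta.to_numpy(), rel=1e-8)

    def test_rank_deficiency_names_collinear_column(self, small_trial):
        *_, table = small_trial
        t2 = CountingProcessTable(
            table.data.assign(age2=2.0 * table.data["age"]),
            table.clock,
            table.covariate_names + ["age2"],
        )
        with pytest.raises(np.linalg.LinAlgError, match="age2|age"):
            fit_cox(t2, ModelSpec(covariates=("age", "age2")))

    def test_loglik_increases_from_null(self, small_trial):
        *_, table = small_trial
        fit = fit_cox(table, ModelSpec(covariates=("age", "sex", "prior_count")))
        assert fit.converged
        assert fit.loglik_final >= fit.loglik_null

    def test_matches_lifelines_time_varying_fitter(self, small_trial):
        """Independent cross-check of the AG fit against lifelines."""
        lifelines = pytest.importorskip("lifelines")
        *_, table = small_trial
        df = table.data.copy()
        # AG model: total-time clock, common baseline
        total = df.sort_values(["subject_id", "stratum"]).copy()
        offs = total.groupby("subject_id")["stop"].shift(1).fillna(0.0)
        cum = total.groupby("subject_id")["stop"].cumsum()
        total["start"] = cum - total["stop"]
        total["stop"] = cum
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            total[["subject_id", "start", "stop", "status", "arm", "age"]],
            id_col="subject_id",
            event_col="status",
            start_col="start",
            stop_col="stop",
        )
        at = CountingProcessTable(total, "total", table.covariate_names)
        fit = fit_cox(at, ModelSpec(clock="total", stratified=False, covariates=("age",)))
        assert fit.beta["arm"] == pytest.approx(ctv.params_["arm"], abs=1e-5)
        assert fit.beta["age"] == pytest.approx(ctv.params_["age"], abs=1e-5)


class TestModelFamilyNesting:
    """Risk-set construction for AG / PWP-TT / PWP-GT on a worked table."""

    def hand_table(self):
        # 5 subjects: events at (10, 30), (20,), (), (15, 40, 60), (25,)
        times = {"a": [10, 30], "b": [20], "c": [], "d": [15, 40, 60], "e": [25]}
        hs = [
            pd.Series(
                {
                    "subject_id": s,
                    "cluster_id": "c0",
                    "arm": int(i % 2),
                }
            )
            for i, s in enumerate(times)
        ]
        from cfrail.dataprep import SubjectEventHistory

        histories = [
            SubjectEventHistory(s, "c0", int(i % 2), times[s], 80.0)
            for i, s in enumerate(times)
        ]
        return histories

    def risk_set_sizes(self, table, spec):
        data = CoxData(table, spec)
        sizes = []
        for b in data.blocks:
            idx = b["idx"]
            for i in sorted(idx[data.status[idx] == 1], key=lambda i: data.stop[i]):
                t = data.stop[i]
                sizes.append(
                    (b["k"], t, sum(1 for j in idx if data.start[j] < t <= data.stop[j]))
                )
        return sorted(sizes)

    def test_ag_unrestricted_risk_sets(self):
        table = build_counting_process(self.hand_table(), 80.0, "total")
        sizes = self.risk_set_sizes(table, ModelSpec(clock="total", stratified=False))
        # AG: everyone under observation is at risk at every event time
        assert sizes == sorted(
            [(1, 10.0, 5), (1, 15.0, 5), (1, 20.0, 5), (1, 25.0, 5), (1, 30.0, 5),
             (1, 40.0, 5), (1, 60.0, 5)]
        )

    def test_pwp_total_time_conditional_risk_sets(self):
        table = build_counting_process(self.hand_table(), 80.0, "total")
        sizes = self.risk_set_sizes(table, ModelSpec(clock="total", stratified=True))
        # hand enumeration: stratum 1 risk sets shrink as events occur;
        # stratum 2 contains subjects with a first event (censored rows
        # stay at risk until their follow-up ends)
        assert sizes == sorted(
            [(1, 10.0, 5), (1, 15.0, 4), (1, 20.0, 3), (1, 25.0, 2),
             (2, 30.0, 4), (2, 40.0, 3), (3, 60.0, 2)]
        )

    def test_pwp_gap_time_risk_sets(self):
        table = build_counting_process(self.hand_table(), 80.0, "gap")
        sizes = self.risk_set_sizes(table, ModelSpec(clock="gap", stratified=True))
        # gap clock: stratum-1 gaps 10,20,15,25; stratum-2 event gaps 20,25
        # with censored gaps 60 (b) and 55 (e) still at risk; stratum-3
        # event gap 20 with a's censored gap 50 at risk
        assert sizes == sorted(
            [(1, 10.0, 5), (1, 15.0, 4), (1, 20.0, 3), (1, 25.0, 2),
             (2, 20.0, 4), (2, 25.0, 3), (3, 20.0, 2)]
        )


class TestRobustCovariance:
    def test_single_subject_clusters_equal_subject_sandwich(self, small_trial):
        *_, table = small_trial
        spec = ModelSpec(covariates=("age",))
        fit = fit_cox(table, spec)
        by_subject = robust_covariance(fit, cluster_ids=fit._data.subject_id)
        one_per = robust_covariance(fit, cluster_ids=fit._data.subject_id.copy())
        pd.testing.assert_frame_equal(by_subject, one_per)

    def test_duplicating_clusters_preserves_estimate(self, small_trial):
        # Breslow ties: duplication rescales every risk-set denominator
        # by 2, leaving the maximiser unchanged (Efron would treat the
        # duplicated events as genuine ties and differ)
        *_, table = small_trial
        spec = ModelSpec(covariates=("age",), ties="breslow")
        fit1 = fit_cox(table, spec)
        dup = table.data.copy()
        dup["subject_id"] = dup["subject_id"].astype(str) + "_dup"
        dup["cluster_id"] = dup["cluster_id"].astype(str) + "_dup"
        doubled = CountingProcessTable(
            pd.concat([table.data, dup], ignore_index=True),
            table.clock,
            table.covariate_names,
        )
        fit2 = fit_cox(doubled, spec)
        assert fit2.beta.to_numpy() == pytest.approx(fit1.beta.to_numpy(), abs=1e-6)
        # information doubles
        assert np.diag(fit2.information) == pytest.approx(
            2 * np.diag(fit1.information), rel=1e-6
        )

    def test_fewer_than_two_clusters_rejected(self, separation_table):
        df = separation_table.data.assign(cluster_id="only")
        table = CountingProcessTable(df, "gap", [])
        fit = fit_cox(table, ModelSpec(ties="breslow"))
        with pytest.raises(ValueError, match="2 clusters"):
            robust_covariance(fit)

    def test_score_residuals_sum_to_score(self, small_trial):
        *_, table = small_trial
        spec = ModelSpec(covariates=("age",), ties="efron")
        data = CoxData(table, spec)
        beta = np.array([0.1, 0.02])
        _, grad, _ = data.loglik(beta)
        resid = data.score_residuals(beta)
        assert resid.sum(axis=0) == pytest.approx(grad, abs=1e-8)


class TestBaselineHazard:
    def test_null_fit_single_stratum_is_nelson_aalen(self):
        rows = [
            ("a", "c", 1, 0.0, 2.0, 1, 0),
            ("b", "c", 1, 0.0, 4.0, 1, 0),
            ("c", "c", 1, 0.0, 6.0, 0, 0),
        ]
        table = make_table(rows)
        data = CoxData(table, ModelSpec())
        jumps = data.breslow_jumps(np.zeros(1))
        times, j = jumps[1]
        assert list(times) == [2.0, 4.0]
        assert j == pytest.approx([1 / 3, 1 / 2])

    def test_cumulative_hazard_non_decreasing(self, small_trial):
        *_, table = small_trial
        fit = fit_cox(table, ModelSpec(covariates=("age",)))
        bh = baseline_cumhaz(fit)
        for k, df in bh.curves.items():
            assert (df["jump"] >= 0).all()
            assert df["cumhaz"].is_monotonic_increasing

    def test_matches_brute_force_accumulation(self, rng):
        histories = random_histories(rng, n_subjects=10)
        table = build_counting_process(histories, 122.0, "gap")
        fit = fit_cox(table, ModelSpec(covariates=("age",), ties="breslow"))
        data = fit._data
        bh = baseline_cumhaz(fit)
        eta = data.X @ fit.beta.to_numpy()
        for b in data.blocks:
            idx = b["idx"]
            acc = 0.0
            curve = bh.curves[b["k"]]
            for t, row in zip(curve["time"], curve.itertuples()):
                rs = [j for j in idx if data.start[j] < t <= data.stop[j]]
                d = sum(1 for j in idx if data.stop[j] == t and data.status[j] == 1)
                acc += d / np.exp(eta[rs]).sum()
                assert row.cumhaz == pytest.approx(acc)


class TestFirth:
    def test_separation_toy_recovers_log3(self, separation_table):
        fit = fit_firth(separation_table, ModelSpec(ties="breslow"))
        assert fit.converged
        assert fit.beta.iloc[0] == pytest.approx(np.log(3), abs=1e-6)

    def test_grid_search_oracle_on_penalised_objective(self, separation_table):
        data = CoxData(separation_table, ModelSpec(ties="breslow"))
        grid = np.arange(-4, 4, 1e-4)
        # closed form: p = e^b/(1+e^b); objective = 1.5 log p + 0.5 log(1-p)
        p = np.exp(grid) / (1 + np.exp(grid))
        objective = 1.5 * np.log(p) + 0.5 * np.log(1 - p)
        best = grid[int(np.argmax(objective))]
        fit = fit_firth(separation_table, ModelSpec(ties="breslow"))
        assert fit.beta.iloc[0] == pytest.approx(best, abs=2e-4)

    def test_agrees_with_unpenalised_on_large_data(self):
        cfg = SimulationConfig(
            n_clusters=30, subjects_per_cluster=40, theta=0.0,
            include_covariates=False, dropout_prob=0.0, seed=17,
        )
        histories, _ = simulate_trial(cfg)
        table = build_counting_process(histories, cfg.window, "gap")
        from cfrail.dataprep import truncate_events

        table = truncate_events(table, 5)
        plain = fit_cox(table, ModelSpec())
        firth = fit_firth(table, ModelSpec())
        # penalty is O(1) against an O(n) likelihood
        assert firth.beta["arm"] == pytest.approx(plain.beta["arm"], abs=5e-3)
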