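"""Likelihood, estimation, model comparison and the bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from pairctmc import (
    CovariateSpec,
    DEFAULT_FULL_RATES,
    DegenerateDesignError,
    InvalidParameterError,
    MismatchedDataError,
    NotNestedError,
    SchemeMismatchError,
    StudyConfig,
    Trajectory,
    aic_compare,
    bootstrap,
    delta_aic_from_lrt,
    exact_loglik,
    fit_session_logs,
    lrt,
    make_study,
    mle_closed_form,
    mle_fit,
)
from pairctmc.ctmc_inference import fit_result_from_dict


def _unit_rates(scheme, **overrides):
    rates = {c: 1.0 for c in scheme.classes}
    rates.update(overrides)
    return rates


class TestExactLoglik:
    def test_single_sojourn_with_transition(self, full_scheme):
        # 2 min in state 5 ending 5->6 with q_5,6 = 0.5 and q_5,1 = 0.1:
        # ln 0.5 - (0.5 + 0.1) * 2
        traj = Trajectory("pair", [(5, 0.0), (6, 2.0)], 2.0)
        rates = _unit_rates(full_scheme, q_5_6=0.5, q_5_1=0.1)
        ll = exact_loglik([traj], full_scheme, rates)
        assert ll == pytest.approx(math.log(0.5) - 0.6 * 2.0, abs=1e-9)
        assert ll == pytest.approx(-1.8931, abs=5e-5)

    def test_fully_censored_sojourn(self, full_scheme):
        traj = Trajectory("pair", [(5, 0.0)], 3.5)
        rates = _unit_rates(full_scheme, q_5_6=0.5, q_5_1=0.1)
        assert exact_loglik([traj], full_scheme, rates) \
            == pytest.approx(-0.6 * 3.5)

    def test_zero_coefficients_reduce_to_baseline(self, full_scheme, small_study):
        trajs = {l.pair_id: [] for l in small_study.logs}
        from pairctmc import encode_pair
        for log in small_study.logs:
            trajs[log.pair_id].append(encode_pair(log))
        rates = _unit_rates(full_scheme)
        base = exact_loglik(trajs, full_scheme, rates)
        zero_coefs = {("x_bold", c): 0.0 for c in full_scheme.classes}
        with_cov = exact_loglik(trajs, full_scheme, rates,
                                coefficients=zero_coefs,
                                cov_spec=CovariateSpec(),
                                cov_values=small_study.covariates)
        assert with_cov == pytest.approx(base)

    def test_nonpositive_rate_on_observed_transition(self, full_scheme):
        traj = Trajectory("pair", [(5, 0.0), (6, 2.0)], 2.0)
        with pytest.raises(InvalidParameterError):
            exact_loglik([traj], full_scheme, _unit_rates(full_scheme, q_5_6=0.0))

    def test_unclassed_edge_signals_scheme_mismatch(self):
        from pairctmc.ctmc_inference import scheme_from_names
        two = scheme_from_names("two_state", "individual")
        traj = Trajectory("pair", [(5, 0.0), (6, 2.0)], 2.0)
        with pytest.raises(SchemeMismatchError):
            exact_loglik([traj], two, {"leave": 1.0, "return": 1.0})


class TestClosedFormMle:
    def test_events_over_exposure(self, full_scheme):
        traj = Trajectory("pair", [(5, 0.0), (6, 2.0)], 2.0)
        with pytest.warns(UserWarning, match="zero exposure"):
            fit = mle_closed_form([traj], full_scheme)
        assert fit.rates["q_5_6"] == pytest.approx(0.5)
        assert fit.rates["q_5_1"] == 0.0
        assert fit.n_events["q_5_6"] == 1
        assert fit.exposure["q_5_1"] == pytest.approx(2.0)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_empty_trajectory_set(self, full_scheme):
        with pytest.raises(ValueError, match="empty"):
            mle_closed_form([], full_scheme)

    def test_pooled_estimate_is_weighted_average(self, small_study, pair_space):
        from pairctmc import tying_scheme
        full = fit_session_logs(small_study.logs, "full")
        mf_fit = fit_session_logs(small_study.logs, "memory_free")
        mf = tying_scheme(pair_space, "memory_free")
        for label in mf.classes:
            edges = mf.edges_of(label)
            per_edge = [full.rates[f"q_{s}_{t}"] for s, t in edges]
            pooled = mf_fit.rates[label]
            assert min(per_edge) - 1e-12 <= pooled <= max(per_edge) + 1e-12
            # and it is exactly the exposure-weighted mean
            weights = [full.exposure[f"q_{s}_{t}"] for s, t in edges]
            expected = np.average(per_edge, weights=weights)
            assert pooled == pytest.approx(expected)

    def test_optimizer_agrees_with_closed_form(self, full_scheme):
        for seed in range(5):
            ds = make_study(StudyConfig(n_pairs=2, sessions_per_pair=1,
                                        session_minutes=20.0, seed=seed))
            cf = fit_session_logs(ds.logs, "full")
            nm = fit_session_logs(ds.logs, "full", numerical=True)
            assert nm.converged
            for c in cf.classes:
                if cf.n_events[c] > 0:
                    assert nm.rates[c] == pytest.approx(cf.rates[c], rel=1e-6)
            assert nm.loglik == pytest.approx(cf.loglik, abs=1e-6)


class TestCovariateFit:
    def test_constant_covariates_are_degenerate(self, small_study):
        cov = small_study.covariates.assign(x_bold=1.0, x_shy=1.0)
        with pytest.raises(DegenerateDesignError):
            fit_session_logs(small_study.logs, "full", covariates=cov)

    def test_both_covariates_add_48_parameters(self, small_study):
        base = fit_session_logs(small_study.logs, "full", numerical=True)
        both = fit_session_logs(small_study.logs, "full",
                                covariates=small_study.covariates)
        assert both.k - base.k == 48
        res = lrt(both, base)
        assert res.df == 48 and res.stat >= 0

    def test_own_effects_only_halves_coefficients(self, small_study):
        both = fit_session_logs(small_study.logs, "full",
                                covariates=small_study.covariates)
        own = fit_session_logs(small_study.logs, "full",
                               covariates=small_study.covariates,
                               cov_spec=CovariateSpec(own_effects_only=True))
        assert both.k - own.k == 24
        assert set(own.coefficients) < set(both.coefficients)
        res = lrt(both, own)
        assert res.df == 24

    def test_centering_defaults_to_covariate_mean(self, small_study):
        fit = fit_session_logs(small_study.logs, "full",
                               covariates=small_study.covariates)
        assert fit.centering["x_bold"] == pytest.approx(
            small_study.covariates["x_bold"].mean())

    def test_recovers_known_effect_direction(self):
        truth = {("x_bold", "q_5_6"): 0.5}
        ds = make_study(StudyConfig(n_pairs=20, sessions_per_pair=2,
                                    coefficient_truth=truth, seed=5))
        spec = CovariateSpec(affected_classes={"x_bold": frozenset({"q_5_6"}),
                                               "x_shy": frozenset()})
        fit = fit_session_logs(ds.logs, "full", covariates=ds.covariates,
                               cov_spec=spec)
        assert fit.converged
        assert fit.coefficients[("x_bold", "q_5_6")] > 0


class TestModelComparison:
    def test_nested_degrees_of_freedom(self, small_study):
        full = fit_session_logs(small_study.logs, "full")
        io = fit_session_logs(small_study.logs, "initiator_only")
        mf = fit_session_logs(small_study.logs, "memory_free")
        assert lrt(full, mf).df == 16
        assert lrt(full, io).df == 8
        assert lrt(io, mf).df == 8

    def test_loglik_monotone_in_model_size(self, small_study):
        full = fit_session_logs(small_study.logs, "full")
        io = fit_session_logs(small_study.logs, "initiator_only")
        mf = fit_session_logs(small_study.logs, "memory_free")
        assert full.loglik >= io.loglik >= mf.loglik

    def test_non_nested_models_refuse_lrt(self, small_study):
        full = fit_session_logs(small_study.logs, "full")
        one_step = fit_session_logs(small_study.logs, "one_step_memory")
        with pytest.raises(NotNestedError):
            lrt(full, one_step)
        delta = aic_compare(full, one_step)
        assert isinstance(delta, float)

    def test_one_step_comparison_favours_generating_model(self, small_study):
        # data were generated under the full 12-state model
        full = fit_session_logs(small_study.logs, "full")
        one_step = fit_session_logs(small_study.logs, "one_step_memory")
        assert aic_compare(full, one_step) > 0

    def test_delta_aic_identity_for_nested_fits(self, small_study):
        full = fit_session_logs(small_study.logs, "full")
        mf = fit_session_logs(small_study.logs, "memory_free")
        res = lrt(full, mf)
        assert aic_compare(full, mf) == pytest.approx(
            delta_aic_from_lrt(res.stat, res.df))

    def test_identical_fits_have_zero_delta(self, small_study):
        a = fit_session_logs(small_study.logs, "full")
        b = fit_session_logs(small_study.logs, "full")
        assert aic_compare(a, b) == 0.0

    def test_different_data_refused(self, small_study):
        other = make_study(StudyConfig(n_pairs=2, sessions_per_pair=1, seed=9))
        a = fit_session_logs(small_study.logs, "full")
        b = fit_session_logs(other.logs, "full")
        with pytest.raises(MismatchedDataError):
            aic_compare(a, b)

    def test_time_unit_scaling(self, small_study):
        per_min = fit_session_logs(small_study.logs, "full", time_unit=60.0)
        per_sec = fit_session_logs(small_study.logs, "full", time_unit=1.0)
        for c in per_min.classes:
            assert per_min.rates[c] == pytest.approx(60.0 * per_sec.rates[c])
        # log-likelihood differences between models are unit-free
        mf_min = fit_session_logs(small_study.logs, "memory_free", time_unit=60.0)
        mf_sec = fit_session_logs(small_study.logs, "memory_free", time_unit=1.0)
        assert per_min.loglik - mf_min.loglik == pytest.approx(
            per_sec.loglik - mf_sec.loglik, abs=1e-6)


class TestFitResultSerialization:
    def test_json_round_trip(self, small_study):
        import json
        fit = fit_session_logs(small_study.logs, "full",
                               covariates=small_study.covariates)
        back = fit_result_from_dict(json.loads(json.dumps(fit.to_dict())))
        assert back.loglik == pytest.approx(fit.loglik)
        assert back.k == fit.k
        assert back.coefficients == fit.coefficients
        assert back.fingerprint == fit.fingerprint
        assert back.scheme.assignment == fit.scheme.assignment


class TestBootstrap:
    def test_reproducible_from_seed(self, small_study):
        est = lambda logs: {"q56": fit_session_logs(logs, "full").rates["q_5_6"]}
        a = bootstrap(small_study.logs, est, B=20, seed=3)
        b = bootstrap(small_study.logs, est, B=20, seed=3)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.ci == b.ci

    def test_constant_estimator_has_zero_width_ci(self, small_study):
        br = bootstrap(small_study.logs, lambda logs: {"c": 7.0}, B=25, seed=0)
        assert br.ci["c"] == (7.0, 7.0)
        assert br.pvalue("c", null=1.0) == pytest.approx(2.0 / 25)

    def test_percentile_interval_level(self, small_study):
        est = lambda logs: {"q56": fit_session_logs(logs, "full").rates["q_5_6"]}
        br = bootstrap(small_study.logs, est, B=200, seed=1)
        lo, hi = br.ci["q56"]
        inside = ((br.replicates["q56"] >= lo) & (br.replicates["q56"] <= hi)).mean()
        assert inside >= 0.95

    def test_failed_replicates_are_redrawn(self, small_study):
        def flaky(logs):
            pairs = {l.pair_id for l in logs}
            if len(pairs) < 4:  # fails when the resample is too concentrated
                raise RuntimeError("degenerate resample")
            return {"n": float(len(pairs))}
        br = bootstrap(small_study.logs, flaky, B=30, seed=2, max_failures=500)
        assert len(br.replicates) == 30
        assert (br.replicates["n"] >= 4).all()

    def test_ratio_pvalue_definition(self, small_study):
        est = lambda logs: {
            "ratio": fit_session_logs(logs, "full").rates["q_5_6"]
            / fit_session_logs(logs, "full").rates["q_5_1"]}
        br = bootstrap(small_study.logs, est, B=40, seed=4)
        r = br.replicates["ratio"].to_numpy()
        expected = 2.0 * min((r <= 1).mean(), (r >= 1).mean())
        assert br.pvalue("ratio") == pytest.approx(max(expected, 2.0 / 40))
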