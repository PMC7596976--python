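import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import exhaz as ex
from exhaz.models import CohortDesign, EmptySegmentError, ParameterVector


def psi_for(spec, beta=None, tau=None, alpha_tilde=None):
    p, k = len(spec.covariates), spec.n_intervals
    return ParameterVector(
        np.zeros(p) if beta is None else np.asarray(beta, float),
        np.full(k, np.log(0.2)) if tau is None else np.asarray(tau, float),
        np.zeros(spec.alpha_shape) if alpha_tilde is None else np.asarray(alpha_tilde, float),
    )


class TestExcessHazard:
    def test_single_interval_constant(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=())
        psi = psi_for(spec, tau=[np.log(0.2)])
        for t in (0.0, 1.0, 5.9):
            assert ex.excess_hazard(t, {}, spec, psi) == pytest.approx(0.2)

    def test_two_intervals_with_covariate(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 1.0, 6.0), covariates=("z",))
        psi = psi_for(spec, beta=[0.3], tau=np.log([0.5, 0.1]))
        assert ex.excess_hazard(2.0, {"z": 1.0}, spec, psi) == pytest.approx(0.1 * np.exp(0.3))

    def test_null_covariate_effect(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=("z",))
        psi0 = psi_for(spec, beta=[0.0], tau=[np.log(0.7)])
        spec_free = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=())
        psi_free = psi_for(spec_free, tau=[np.log(0.7)])
        for z in (-3.0, 0.0, 11.0):
            assert ex.excess_hazard(2.0, {"z": z}, spec, psi0) == ex.excess_hazard(2.0, {}, spec_free, psi_free)

    def test_beyond_last_cut_rejected(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=())
        with pytest.raises(ValueError):
            ex.excess_hazard(6.5, {}, spec, psi_for(spec))


class TestCumulativeExcessHazard:
    def test_single_interval_rt(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=())
        psi = psi_for(spec, tau=[np.log(0.2)])
        assert ex.cumulative_excess_hazard(3.0, {}, spec, psi) == pytest.approx(0.6)

    def test_hand_computed_split(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 1.0, 6.0), covariates=())
        psi = psi_for(spec, tau=np.log([0.5, 0.1]))
        assert ex.cumulative_excess_hazard(2.0, {}, spec, psi) == pytest.approx(0.6)

    def test_derivative_is_hazard(self):
        spec = ex.ExcessModelSpec(cuts=(0.0, 1.0, 6.0), covariates=("z",))
        psi = psi_for(spec, beta=[0.2], tau=np.log([0.5, 0.1]))
        h = 1e-7
        z = {"z": 0.4}
        d = (
            ex.cumulative_excess_hazard(2.0 + h, z, spec, psi)
            - ex.cumulative_excess_hazard(2.0 - h, z, spec, psi)
        ) / (2 * h)
        assert d == pytest.approx(ex.excess_hazard(2.0, z, spec, psi), rel=1e-8)


class TestLogLikelihood:
    def test_alpha_one_nests_esteve(self, small_cohort, small_spec, gompertz_table):
        psi = psi_for(small_spec, beta=[0.3, -0.2], tau=np.full(small_spec.n_intervals, np.log(0.15)))
        spec_e = replace(small_spec, kind="esteve", breakpoints=())
        psi_e = ParameterVector(psi.beta, psi.tau, np.empty((0, 0)))
        l3 = ex.log_likelihood(small_cohort, gompertz_table, small_spec, psi)
        l1 = ex.log_likelihood(small_cohort, gompertz_table, spec_e, psi_e)
        assert l3 == l1

    def test_b_zero_nests_touraine(self, small_cohort, small_spec, gompertz_table):
        spec_b0 = replace(small_spec, breakpoints=())
        spec_t = replace(small_spec, kind="touraine", breakpoints=())
        psi = ParameterVector(
            np.array([0.3, -0.2]),
            np.full(small_spec.n_intervals, np.log(0.15)),
            np.array([[0.2], [-0.1]]),
        )
        assert ex.log_likelihood(small_cohort, gompertz_table, spec_b0, psi) == ex.log_likelihood(
            small_cohort, gompertz_table, spec_t, psi
        )

    def test_single_subject_scalar_oracle(self, constant_table):
        """One death, one interval, constant table: hand-written formula."""
        t, age, year = 2.5, 68.3, 1990
        lam_e, alpha, beta_z = 0.3, 1.4, 0.25
        data = pd.DataFrame({
            "t": [t], "delta": [1], "age": [age], "diag_year": [year],
            "x": [0], "z": [1.0],
        })
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=("z",), kind="touraine", n_levels=1)
        psi = ParameterVector(np.array([beta_z]), np.array([np.log(lam_e)]), np.array([[np.log(alpha)]]))
        lam_e_t = lam_e * np.exp(beta_z)
        expect = (
            -lam_e_t * t - alpha * 0.02 * t + np.log(lam_e_t + alpha * 0.02)
        )
        got = ex.log_likelihood(data, constant_table, spec, psi)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_permutation_invariance(self, small_cohort, small_spec, gompertz_table):
        psi = psi_for(small_spec, beta=[0.1, 0.1], tau=np.full(small_spec.n_intervals, np.log(0.2)),
                      alpha_tilde=0.1 * np.ones(small_spec.alpha_shape))
        shuffled = small_cohort.sample(frac=1.0, random_state=7).reset_index(drop=True)
        l0 = ex.log_likelihood(small_cohort, gompertz_table, small_spec, psi)
        l1 = ex.log_likelihood(shuffled, gompertz_table, small_spec, psi)
        assert l0 == pytest.approx(l1, rel=1e-12)

    def test_nonfinite_flags_subject(self, constant_table):
        data = pd.DataFrame({
            "t": [1.0, 2.0], "delta": [1, 1], "age": [50.0, 60.0],
            "diag_year": [1990, 1990], "x": [0, 0],
        })
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=(), kind="touraine", n_levels=1)
        psi = ParameterVector(np.empty(0), np.array([800.0]), np.array([[0.0]]))
        with pytest.raises(ValueError, match="subject"):
            ex.log_likelihood(data, constant_table, spec, psi)


class TestScore:
    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_finite_differences(self, small_cohort, small_spec, gompertz_table, seed):
        rng = np.random.default_rng(seed)
        psi = ParameterVector(
            rng.normal(0, 0.3, 2),
            rng.normal(np.log(0.15), 0.3, small_spec.n_intervals),
            rng.normal(0, 0.3, small_spec.alpha_shape),
        )
        design = CohortDesign(small_cohort, gompertz_table, small_spec)
        g = design.score(psi)
        theta = psi.pack()
        fd = np.empty_like(theta)
        for j in range(theta.size):
            e = np.zeros_like(theta)
            e[j] = 1e-6 * (1 + abs(theta[j]))
            fd[j] = (
                design.loglik(ParameterVector.unpack(theta + e, small_spec))
                - design.loglik(ParameterVector.unpack(theta - e, small_spec))
            ) / (2 * e[j])
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-6)

    def test_zero_at_mle(self, small_cohort, small_spec, gompertz_table):
        res = ex.fit(small_cohort, gompertz_table, small_spec)
        g = ex.score_vector(small_cohort, gompertz_table, small_spec, res.params)
        assert np.max(np.abs(g)) <= 1e-4

    def test_beta_tau_block_matches_esteve(self, small_cohort, small_spec, gompertz_table):
        psi = psi_for(small_spec, beta=[0.2, -0.1], tau=np.full(small_spec.n_intervals, np.log(0.2)))
        spec_e = replace(small_spec, kind="esteve", breakpoints=())
        psi_e = ParameterVector(psi.beta, psi.tau, np.empty((0, 0)))
        g3 = ex.score_vector(small_cohort, gompertz_table, small_spec, psi)
        g1 = ex.score_vector(small_cohort, gompertz_table, spec_e, psi_e)
        np.testing.assert_array_equal(g3[: g1.size], g1)


class TestFit:
    def test_refit_from_mle_is_fixed_point(self, small_cohort, small_spec, gompertz_table):
        res = ex.fit(small_cohort, gompertz_table, small_spec)
        res2 = ex.fit(small_cohort, gompertz_table, small_spec, init=res.params)
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-8)

    def test_aic_identity(self, small_cohort, small_spec, gompertz_table):
        res = ex.fit(small_cohort, gompertz_table, small_spec)
        assert res.aic == 2 * res.n_params - 2 * res.loglik

    def test_covariance_symmetric_psd(self, small_cohort, sim_config, gompertz_table):
        spec = ex.model_spec_for(small_cohort, sim_config, ex.scenario("A"), "touraine")
        res = ex.fit(small_cohort, gompertz_table, spec)
        assert res.converged
        np.testing.assert_allclose(res.cov, res.cov.T, atol=1e-12 * np.abs(res.cov).max())
        assert np.all(np.linalg.eigvalsh(res.cov) > -1e-8 * np.abs(res.cov).max())

    def test_empty_segment_reported(self, small_cohort, sim_config, gompertz_table):
        # a breakpoint above every attained age leaves the last segment empty
        spec = ex.model_spec_for(small_cohort, sim_config, ex.scenario("A"), "breakpoint", (120.0,))
        with pytest.raises(EmptySegmentError, match="segment"):
            ex.fit(small_cohort, gompertz_table, spec)

    def test_literal_and_segment_conventions_differ(self, small_cohort, small_spec, gompertz_table):
        """The two survival conventions agree only when no follow-up crosses a breakpoint."""
        psi = psi_for(small_spec, beta=[0.3, -0.2],
                      tau=np.full(small_spec.n_intervals, np.log(0.15)),
                      alpha_tilde=[[0.5, 0.0, -0.4], [0.2, 0.6, -0.2]])
        lit = replace(small_spec, cumulative="literal")
        l_seg = ex.log_likelihood(small_cohort, gompertz_table, small_spec, psi)
        l_lit = ex.log_likelihood(small_cohort, gompertz_table, lit, psi)
        assert l_seg != l_lit
        # with all alpha equal across segments the two conventions coincide
        psi_flat = psi_for(small_spec, beta=[0.3, -0.2],
                           tau=np.full(small_spec.n_intervals, np.log(0.15)),
                           alpha_tilde=0.3 * np.ones(small_spec.alpha_shape) * 0 + 0.3)
        assert ex.log_likelihood(small_cohort, gompertz_table, small_spec, psi_flat) == pytest.approx(
            ex.log_likelihood(small_cohort, gompertz_table, lit, psi_flat), rel=1e-12
        )


class TestWaldSummary:
    def _result(self, beta, se):
        spec = ex.ExcessModelSpec(cuts=(0.0, 6.0), covariates=("z",))
        psi = ParameterVector(np.array([beta]), np.array([np.log(0.2)]), np.empty((0, 0)))
        cov = np.diag([se**2, 0.01])
        return ex.FitResult(
            spec=spec, params=psi, cov=cov, loglik=-10.0, aic=24.0,
            converged=True, message="", n_subjects=10, n_deaths=5, n_params=2,
        )

    def test_null_effect_interval(self):
        summ = ex.wald_summary(self._result(0.0, 0.1))
        row = summ[summ["term"] == "z"].iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["lo"] == pytest.approx(np.exp(-1.959964 * 0.1), rel=1e-5)
        assert row["hi"] == pytest.approx(np.exp(+1.959964 * 0.1), rel=1e-5)

    def test_alpha_interval_straddles_one(self, small_cohort, small_spec, gompertz_table):
        res = ex.fit(small_cohort, gompertz_table, small_spec)
        summ = ex.wald_summary(res)
        alpha_rows = summ[summ["kind"] == "alpha"]
        assert len(alpha_rows) == np.prod(small_spec.alpha_shape)
        near_null = alpha_rows[np.abs(alpha_rows["log_estimate"]) < 0.05]
        for _, r in near_null.iterrows():
            assert r["lo"] < 1.0 < r["hi"]

    def test_degenerate_zero_se(self):
        summ = ex.wald_summary(self._result(0.4, 0.0))
        row = summ[summ["term"] == "z"].iloc[0]
        assert row["lo"] == row["estimate"] == row["hi"]


def test_loglik_ordering_of_nested_models(small_cohort, sim_config, gompertz_table):
    """Maximized log-likelihoods are ordered by nesting: Model 3 >= 2 >= 1."""
    scen = ex.scenario("A")
    l1 = ex.fit(small_cohort, gompertz_table, ex.model_spec_for(small_cohort, sim_config, scen, "esteve")).loglik
    l2 = ex.fit(small_cohort, gompertz_table, ex.model_spec_for(small_cohort, sim_config, scen, "touraine")).loglik
    l3 = ex.fit(small_cohort, gompertz_table, ex.model_spec_for(small_cohort, sim_config, scen, "breakpoint", (75.0,))).loglik
    assert l3 >= l2 - 1e-6
    assert l2 >= l1 - 1e-6
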