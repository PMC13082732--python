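import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import jointbhm as j
from jointbhm.data import LongTableDataset
from jointbhm.exceptions import InvalidArgumentError, SpecError
from jointbhm.model import (
    ModelFrame,
    ModelSpec,
    ParameterState,
    finite_difference_grad,
    grad_log_posterior,
    integrated_loglik_subject,
    linear_predictor,
    log_posterior_unnormalized,
    log_prior,
    loglik_binary_probit,
    loglik_continuous,
    logpost_and_grad_unconstrained,
    marginal_loglik_continuous_subject,
)
from jointbhm.priors import (
    HalfCauchy,
    InverseWishart,
    PriorConfig,
    chol_from_unconstrained,
    chol_log_jacobian,
)

from .conftest import conjugate_gaussian_spec, conjugate_posterior, make_empty_dataset


def _joint_state(frame: ModelFrame, rng: np.random.Generator) -> ParameterState:
    q = frame.q
    A = rng.standard_normal((q, q)) * 0.3
    Sigma = A @ A.T + 0.5 * np.eye(q) if q else np.zeros((0, 0))
    return ParameterState(
        beta_y1=rng.standard_normal(frame.p1) * 0.5,
        beta_y2=rng.standard_normal(frame.p2) * 0.5,
        sigma2_y1=float(rng.uniform(0.5, 2.0)),
        U=rng.standard_normal((frame.N, q)) * 0.4,
        Sigma_u=Sigma,
    )


@pytest.fixture(scope="module")
def joint_frame(tiny_data):
    spec = ModelSpec.from_structure("full", prior=j.preset("mcmcglmm_like"))
    return ModelFrame(tiny_data, spec)


class TestLinearPredictor:
    def test_all_zero(self, tiny_data, joint_frame):
        spec = joint_frame.spec
        st0 = ParameterState(
            np.zeros(4), np.zeros(4), 1.0, np.zeros((4, 4)), np.eye(4)
        )
        eta = linear_predictor(st0, tiny_data, spec, "y1", joint_frame)
        np.testing.assert_array_equal(eta, np.zeros(tiny_data.n_rows))

    def test_intercept_only_constant(self, tiny_data):
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=("intercept",), prior=PriorConfig(),
        )
        fr = ModelFrame(tiny_data, spec)
        st0 = ParameterState(np.array([2.0]), np.array([0.0]), 1.0,
                             np.zeros((fr.N, 2)), np.eye(2))
        eta = linear_predictor(st0, tiny_data, spec, "y1", fr)
        np.testing.assert_allclose(eta, 2.0)

    def test_brute_force_oracle(self, tiny_data, joint_frame):
        rng = np.random.default_rng(0)
        state = _joint_state(joint_frame, rng)
        fr = joint_frame
        for resp, X, beta, cols in (
            ("y1", fr.X1, state.beta_y1, fr.u_cols["y1"]),
            ("y2", fr.X2, state.beta_y2, fr.u_cols["y2"]),
        ):
            eta = linear_predictor(state, tiny_data, fr.spec, resp, fr)
            expected = np.array(
                [
                    X[i] @ beta + fr.Z[i] @ state.U[fr.codes[i], cols]
                    for i in range(fr.n)
                ]
            )
            np.testing.assert_allclose(eta, expected, atol=1e-12)

    def test_unknown_response(self, tiny_data, joint_frame):
        with pytest.raises(SpecError):
            linear_predictor(
                _joint_state(joint_frame, np.random.default_rng(0)),
                tiny_data, joint_frame.spec, "y3", joint_frame,
            )


class TestLoglikContinuous:
    def test_single_obs_at_mean(self):
        from .conftest import single_row_dataset

        data = single_row_dataset(y1=0.0)
        spec = conjugate_gaussian_spec()
        state = ParameterState(np.array([0.0]), np.zeros(0), 1.0,
                               np.zeros((1, 0)), np.zeros((0, 0)))
        assert loglik_continuous(state, data, spec) == pytest.approx(
            -0.918938533, abs=1e-8
        )

    def test_empty_dataset(self):
        data = make_empty_dataset()
        spec = conjugate_gaussian_spec()
        state = ParameterState(np.array([0.0]), np.zeros(0), 1.0,
                               np.zeros((0, 0)), np.zeros((0, 0)))
        assert loglik_continuous(state, data, spec) == 0.0

    def test_textbook_density_oracle(self, tiny_data, joint_frame):
        rng = np.random.default_rng(1)
        state = _joint_state(joint_frame, rng)
        fr = joint_frame
        eta = linear_predictor(state, tiny_data, fr.spec, "y1", fr)
        expected = float(
            np.sum(stats.norm.logpdf(tiny_data.y1, eta, math.sqrt(state.sigma2_y1)))
        )
        got = loglik_continuous(state, tiny_data, fr.spec, fr)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance(self, tiny_data, joint_frame):
        state = _joint_state(joint_frame, np.random.default_rng(2))
        state.sigma2_y1 = -1.0
        with pytest.raises(InvalidArgumentError):
            loglik_continuous(state, tiny_data, joint_frame.spec, joint_frame)


class TestLoglikProbit:
    def test_eta_zero(self):
        from .conftest import single_row_dataset

        data = single_row_dataset(y2=1)
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=(), responses=("y2",), prior=PriorConfig(),
        )
        state = ParameterState(np.zeros(0), np.array([0.0]), 1.0,
                               np.zeros((1, 0)), np.zeros((0, 0)))
        assert loglik_binary_probit(state, data, spec) == pytest.approx(
            -0.693147181, abs=1e-8
        )

    def test_saturated(self):
        from .conftest import single_row_dataset

        data = single_row_dataset(y2=1)
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=(), responses=("y2",), prior=PriorConfig(),
        )
        state = ParameterState(np.zeros(0), np.array([8.0]), 1.0,
                               np.zeros((1, 0)), np.zeros((0, 0)))
        assert abs(loglik_binary_probit(state, data, spec)) < 1e-6

    def test_quadrature_oracle(self, tiny_data, joint_frame):
        # integrate the truncated-latent density row by row
        rng = np.random.default_rng(3)
        state = _joint_state(joint_frame, rng)
        fr = joint_frame
        eta = linear_predictor(state, tiny_data, fr.spec, "y2", fr)
        rows = rng.choice(fr.n, size=10, replace=False)
        expected = 0.0
        for i in rows:
            if fr.y2[i] == 1:
                p, _ = integrate.quad(lambda t: stats.norm.pdf(t, eta[i], 1), 0, np.inf)
            else:
                p, _ = integrate.quad(lambda t: stats.norm.pdf(t, eta[i], 1), -np.inf, 0)
            expected += math.log(p)
        sub = tiny_data.subset(np.isin(np.arange(fr.n), rows))
        got = loglik_binary_probit(state, sub, fr.spec)
        assert got == pytest.approx(expected, abs=1e-8)


class TestLogPrior:
    def test_half_cauchy_at_zero(self):
        assert HalfCauchy(1.0).logpdf(0.0) == pytest.approx(math.log(2 / math.pi), abs=1e-9)
        assert HalfCauchy(1.0).logpdf(0.0) == pytest.approx(-0.451582705, abs=1e-8)

    def test_random_effect_term_at_identity(self, tiny_data):
        # flat beta + fixed sigma2 isolates the U and Sigma_u contributions
        spec = ModelSpec(
            structure="random_intercept",
            fixed_y1=("intercept",), fixed_y2=("intercept",),
            random_covariates=("intercept",),
            prior=PriorConfig(beta_scale=None, sigma_u=InverseWishart()),
            fix_sigma2=1.0,
        )
        fr = ModelFrame(tiny_data, spec)
        state = ParameterState(np.zeros(1), np.zeros(1), 1.0,
                               np.zeros((fr.N, 2)), np.eye(2))
        got = log_prior(state, spec.prior, fr)
        iw_part = stats.invwishart.logpdf(np.eye(2), df=3, scale=np.eye(2))
        assert got - iw_part == pytest.approx(-fr.N * math.log(2 * math.pi), abs=1e-10)

    def test_inverse_wishart_textbook_formula(self):
        # manual density vs implementation at Sigma = I, nu = 3, S = I, q = 2
        q, nu = 2, 3.0
        from scipy.special import multigammaln

        manual = (
            0.5 * nu * 0  # log det S = 0
            - 0.5 * nu * q * math.log(2)
            - multigammaln(nu / 2, q)
            - 0.5 * (nu + q + 1) * 0  # log det Sigma = 0
            - 0.5 * q  # trace(S Sigma^-1) = q
        )
        got = InverseWishart(nu, np.eye(q)).logpdf(np.eye(q))
        assert got == pytest.approx(manual, abs=1e-10)

    def test_outside_support_is_minus_inf(self, tiny_data, joint_frame):
        state = _joint_state(joint_frame, np.random.default_rng(4))
        state.Sigma_u = np.array([[1.0, 2.0], [2.0, 1.0], ])  # not PD (wrong dim ok?)
        state.Sigma_u = -np.eye(joint_frame.q)
        assert log_prior(state, joint_frame.spec.prior, joint_frame) == -np.inf


class TestLogPosterior:
    def test_flat_prior_limit(self, tiny_data):
        spec = ModelSpec(
            structure="full",
            fixed_y1=("intercept", "ultrasound"), fixed_y2=("intercept", "ultrasound"),
            random_covariates=(),
            prior=PriorConfig(beta_scale=None),
            fix_sigma2=1.0,
        )
        state = ParameterState(np.array([0.3, 0.2]), np.array([0.1, -0.4]), 1.0,
                               np.zeros((tiny_data.n_patients, 0)), np.zeros((0, 0)))
        lp = log_posterior_unnormalized(state, tiny_data, spec)
        ll = loglik_continuous(state, tiny_data, spec) + loglik_binary_probit(
            state, tiny_data, spec
        )
        assert lp == pytest.approx(ll, abs=1e-10)

    def test_independent_recomputation_toy(self):
        # 3-patient toy recomputed from raw density formulas
        data = j.simulate_dataset(j.make_design(3, 1, 1, 2), j.aod_like_truth(), 8)
        spec = ModelSpec.from_structure("random_intercept", prior=j.preset("mcmcglmm_like"))
        fr = ModelFrame(data, spec)
        rng = np.random.default_rng(5)
        state = _joint_state(fr, rng)
        got = log_posterior_unnormalized(state, data, spec, fr)

        X1 = data.design_matrix(spec.fixed_y1)
        X2 = data.design_matrix(spec.fixed_y2)
        codes = data.patient_codes()
        eta1 = X1 @ state.beta_y1 + state.U[codes, 0]
        eta2 = X2 @ state.beta_y2 + state.U[codes, 1]
        manual = float(
            np.sum(stats.norm.logpdf(data.y1, eta1, math.sqrt(state.sigma2_y1)))
        )
        manual += float(np.sum(stats.norm.logcdf((2 * data.y2 - 1) * eta2)))
        manual += float(np.sum(stats.norm.logpdf(state.beta_y1, 0, 10)))
        manual += float(np.sum(stats.norm.logpdf(state.beta_y2, 0, 10)))
        manual += float(stats.invgamma.logpdf(state.sigma2_y1, 0.01, scale=0.01))
        manual += float(stats.invwishart.logpdf(state.Sigma_u, df=3, scale=np.eye(2)))
        manual += float(
            np.sum(stats.multivariate_normal.logpdf(state.U, np.zeros(2), state.Sigma_u))
        )
        assert got == pytest.approx(manual, abs=1e-10)

    def test_row_order_invariance(self, tiny_data, joint_frame):
        rng = np.random.default_rng(6)
        state = _joint_state(joint_frame, rng)
        lp = log_posterior_unnormalized(state, tiny_data, joint_frame.spec, joint_frame)
        perm = rng.permutation(tiny_data.n_rows)
        shuffled = j.LongTableDataset(
            tiny_data.df.iloc[perm].reset_index(drop=True), dict(tiny_data.metadata)
        )
        lp2 = log_posterior_unnormalized(state, shuffled, joint_frame.spec)
        assert lp == pytest.approx(lp2, abs=1e-9)


class TestGradient:
    @pytest.mark.parametrize("preset_name", ["mcmcglmm_like", "brms_like"])
    def test_finite_difference_oracle(self, tiny_data, preset_name):
        spec = ModelSpec.from_structure("full", prior=j.preset(preset_name))
        fr = ModelFrame(tiny_data, spec)
        rng = np.random.default_rng(7)
        v = 0.3 * rng.standard_normal(fr.dim)
        _, g = logpost_and_grad_unconstrained(v, fr)
        fd = finite_difference_grad(
            lambda x: logpost_and_grad_unconstrained(x, fr)[0], v
        )
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-6)
        assert rel.max() < 1e-4

    def test_zero_at_conjugate_mode(self, tiny_data):
        spec = conjugate_gaussian_spec(covs=("intercept", "ultrasound"))
        fr = ModelFrame(tiny_data, spec)
        mean, _ = conjugate_posterior(tiny_data, ("intercept", "ultrasound"), 1.0, 1.0)
        g = grad_log_posterior(mean, fr)
        assert np.linalg.norm(g) < 1e-6

    def test_probit_gradient_closed_form(self):
        from .conftest import single_row_dataset

        x_val = 1.7
        data = single_row_dataset(y2=1, x1=x_val)
        spec = ModelSpec(
            structure="full", fixed_y1=("intercept",), fixed_y2=("ultrasound",),
            random_covariates=(), responses=("y2",),
            prior=PriorConfig(beta_scale=None),
        )
        fr = ModelFrame(data, spec)
        _, g = logpost_and_grad_unconstrained(np.zeros(fr.dim), fr)
        assert g[0] == pytest.approx(0.797884561 * x_val, abs=1e-8)


class TestTransforms:
    def test_round_trip(self, joint_frame):
        rng = np.random.default_rng(8)
        state = _joint_state(joint_frame, rng)
        v = joint_frame.to_unconstrained(state)
        back = joint_frame.from_unconstrained(v)
        np.testing.assert_allclose(back.beta_y1, state.beta_y1, atol=1e-12)
        np.testing.assert_allclose(back.sigma2_y1, state.sigma2_y1, rtol=1e-12)
        np.testing.assert_allclose(back.Sigma_u, state.Sigma_u, atol=1e-12)
        np.testing.assert_allclose(back.U, state.U, atol=1e-12)

    def test_unit_variance_maps_to_zero(self, joint_frame):
        state = _joint_state(joint_frame, np.random.default_rng(9))
        state.sigma2_y1 = 1.0
        v = joint_frame.to_unconstrained(state)
        assert v[joint_frame.sl_t][0] == pytest.approx(0.0, abs=1e-14)

    def test_wrong_length_rejected(self, joint_frame):
        with pytest.raises(InvalidArgumentError):
            joint_frame.from_unconstrained(np.zeros(joint_frame.dim + 1))

    def test_chol_jacobian_vs_numeric(self):
        # numeric determinant of d(tril Sigma) / d c for q = 2
        q = 2
        rng = np.random.default_rng(10)
        c = rng.standard_normal(3) * 0.5

        def sigma_tril(cv):
            L = chol_from_unconstrained(cv, q)
            S = L @ L.T
            return S[np.tril_indices(q)]

        h = 1e-6
        Jm = np.zeros((3, 3))
        for i in range(3):
            cp, cm = c.copy(), c.copy()
            cp[i] += h
            cm[i] -= h
            Jm[:, i] = (sigma_tril(cp) - sigma_tril(cm)) / (2 * h)
        numeric = math.log(abs(np.linalg.det(Jm)))
        assert numeric == pytest.approx(chol_log_jacobian(c, q), rel=1e-5)

    def test_named_row_round_trip(self, joint_frame):
        state = _joint_state(joint_frame, np.random.default_rng(11))
        row = joint_frame.state_to_row(state)
        assert len(row) == len(joint_frame.constrained_names)
        back = joint_frame.row_to_state(row)
        np.testing.assert_allclose(back.Sigma_u, state.Sigma_u, atol=1e-10)
        np.testing.assert_allclose(back.beta_y2, state.beta_y2, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(t=st.floats(-3, 3), off=st.floats(-1, 1), d2=st.floats(-1.5, 1.5))
    def test_transform_bijective_property(self, t, off, d2):
        q = 2
        c = np.array([t, off, d2])
        L = chol_from_unconstrained(c, q)
        from jointbhm.priors import unconstrained_from_chol

        np.testing.assert_allclose(unconstrained_from_chol(L), c, atol=1e-12)


class TestIntegratedLoglik:
    @pytest.fixture()
    def cont_frame(self):
        data = j.simulate_dataset(j.make_design(3, 2, 2, 2), j.aod_like_truth(), 7)
        spec = ModelSpec(
            structure="random_intercept",
            fixed_y1=("intercept", "ultrasound"), fixed_y2=("intercept",),
            random_covariates=("intercept",), responses=("y1",), prior=PriorConfig(),
        )
        return ModelFrame(data, spec)

    def test_point_mass_limit(self, cont_frame):
        from jointbhm.model import pointwise_loglik_state

        st0 = ParameterState(np.array([0.4, 0.6]), np.zeros(0), 0.8,
                             np.zeros((3, 1)), np.zeros((1, 1)))
        rows = np.flatnonzero(cont_frame.codes == 1)
        cond = pointwise_loglik_state(st0, cont_frame)[rows].sum()
        assert integrated_loglik_subject(st0, cont_frame, 1) == pytest.approx(
            cond, abs=1e-10
        )

    def test_closed_form_marginal(self, cont_frame):
        st0 = ParameterState(np.array([0.4, 0.6]), np.zeros(0), 0.8,
                             np.zeros((3, 1)), np.array([[0.5]]))
        for pc in range(3):
            got = integrated_loglik_subject(st0, cont_frame, pc, n_nodes=20)
            exact = marginal_loglik_continuous_subject(st0, cont_frame, pc)
            assert got == pytest.approx(exact, abs=1e-8)

    def test_node_doubling_converged(self, tiny_data):
        spec = ModelSpec.from_structure("random_intercept", prior=j.preset("mcmcglmm_like"))
        fr = ModelFrame(tiny_data, spec)
        st0 = ParameterState(np.full(4, 0.2), np.full(4, 0.1), 0.9,
                             np.zeros((fr.N, 2)), np.diag([0.4, 0.3]))
        a = integrated_loglik_subject(st0, fr, 0, n_nodes=20)
        b = integrated_loglik_subject(st0, fr, 0, n_nodes=40)
        assert abs(a - b) < 1e-8

    def test_invalid_nodes(self, cont_frame):
        st0 = ParameterState(np.array([0.4, 0.6]), np.zeros(0), 0.8,
                             np.zeros((3, 1)), np.array([[0.5]]))
        with pytest.raises(InvalidArgumentError):
            integrated_loglik_subject(st0, cont_frame, 0, n_nodes=0)

    def test_non_spd_sigma_rejected(self, cont_frame):
        st0 = ParameterState(np.array([0.4, 0.6]), np.zeros(0), 0.8,
                             np.zeros((3, 1)), np.array([[-0.5]]))
        with pytest.raises(InvalidArgumentError):
            integrated_loglik_subject(st0, cont_frame, 0)


class TestSpecValidation:
    def test_null_structure_constraints(self):
        with pytest.raises(SpecError):
            ModelSpec(structure="null", fixed_y1=("intercept", "leg"),
                      fixed_y2=("intercept",), random_covariates=("intercept",),
                      prior=PriorConfig())

    def test_only_probit(self):
        with pytest.raises(SpecError):
            ModelSpec(structure="null", fixed_y1=("intercept",),
                      fixed_y2=("intercept",), random_covariates=("intercept",),
                      link="logit", prior=PriorConfig())

    def test_unknown_covariate(self):
        with pytest.raises(SpecError):
            ModelSpec(structure="full", fixed_y1=("intercept", "age"),
                      fixed_y2=("intercept",), random_covariates=("intercept",),
                      prior=PriorConfig())

    def test_serialization_round_trip(self):
        spec = ModelSpec.from_structure("full", prior=j.preset("brms_like"))
        back = ModelSpec.from_dict(spec.to_dict())
        assert back.to_dict() == spec.to_dict()
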