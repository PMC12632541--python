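"""Rice/Woolfson amplitude likelihood, gradients, and the total score."""

import math

import numpy as np
import pytest
import sympy
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from msxref.crystal_core import (AtomicState, MultiStateModel, ReflectionSet,
                                 WeightMatrix)
from msxref.forward_model import StateScattering, compute_msf
from msxref.likelihood import (dataset_neg_log_likelihood,
                               joint_neg_log_likelihood, log_p_amplitude,
                               neg_log_p_derivative, quadratic_gradient_weights,
                               total_score)

PARAM_GRID = [
    # (f_model, alpha, beta, epsilon)
    (5.0, 0.9, 4.0, 1),
    (0.0, 1.0, 2.0, 2),
    (20.0, 1.0, 0.5, 1),
    (1.0, 0.3, 10.0, 4),
]


class TestLogDensity:
    def test_rayleigh_limit_closed_form(self):
        # acentric, alpha*F_M = 0, eps*beta = 1, F_O = 1 -> log 2 - 1
        assert log_p_amplitude(1.0, 0.0, 1.0, 1.0, 1, False) == \
            pytest.approx(math.log(2.0) - 1.0, rel=1e-12)

    def test_acentric_matches_arbitrary_precision_oracle(self):
        # independent high-precision evaluation with sympy
        fo, fm, a, b, eps = 10, 9, 1, 4, 1
        expr = sympy.log(2 * sympy.Integer(fo) / (eps * b)) \
            - sympy.Rational(fo**2 + a**2 * fm**2, eps * b) \
            + sympy.log(sympy.besseli(0, sympy.Rational(2 * a * fo * fm, eps * b)))
        oracle = float(expr.evalf(30))
        assert log_p_amplitude(fo, fm, a, b, eps, False) == pytest.approx(oracle, rel=1e-10)

    def test_centric_matches_arbitrary_precision_oracle(self):
        fo, fm, a, b, eps = 10, 9, 1, 4, 1
        expr = sympy.log(sympy.sqrt(sympy.Rational(2, 1) / (sympy.pi * eps * b))) \
            - sympy.Rational(fo**2 + a**2 * fm**2, 2 * eps * b) \
            + sympy.log(sympy.cosh(sympy.Rational(a * fo * fm, eps * b)))
        oracle = float(expr.evalf(30))
        assert log_p_amplitude(fo, fm, a, b, eps, True) == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("centric", [False, True])
    @pytest.mark.parametrize("fm,alpha,beta,eps", PARAM_GRID)
    def test_density_normalization_by_quadrature(self, centric, fm, alpha, beta, eps):
        def pdf(fo):
            return math.exp(log_p_amplitude(fo, fm, alpha, beta, eps, centric))

        peak = max(alpha * fm, math.sqrt(eps * beta))
        total = 0.0
        edges = [0.0, 0.5 * peak, peak, 2.0 * peak, 4.0 * peak, np.inf]
        for lo, hi in zip(edges[:-1], edges[1:]):
            part, _ = quad(pdf, lo, hi, limit=200)
            total += part
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_no_overflow_for_huge_bessel_arguments(self):
        val = log_p_amplitude(1e6, 1e6, 1.0, 1.0, 1, False)
        assert np.isfinite(val)
        val_c = log_p_amplitude(1e6, 1e6, 1.0, 1.0, 1, True)
        assert np.isfinite(val_c)

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError, match="beta"):
            log_p_amplitude(1.0, 1.0, 1.0, 0.0, 1, False)


class TestDerivative:
    @pytest.mark.parametrize("centric", [False, True])
    def test_matches_finite_differences_on_grid(self, centric):
        rng = np.random.default_rng(0)
        for _ in range(20):
            fo = rng.uniform(0.5, 30)
            fm = rng.uniform(0.1, 30)
            alpha, beta, eps = rng.uniform(0.2, 1.5), rng.uniform(0.5, 10), 1
            h = 1e-6 * max(fm, 1.0)
            fd = (-(log_p_amplitude(fo, fm + h, alpha, beta, eps, centric))
                  + log_p_amplitude(fo, fm - h, alpha, beta, eps, centric)) / (2 * h)
            an = neg_log_p_derivative(fo, fm, alpha, beta, eps, centric)
            assert float(an) == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_sign_flips_across_optimum_once(self):
        """-log p is unimodal in F_M: the gradient changes sign exactly once."""
        fo, alpha, beta, eps = 10.0, 1.0, 0.5, 1
        fms = np.linspace(1e-3, 30, 4000)
        d = neg_log_p_derivative(fo, fms, alpha, beta, eps, False)
        signs = np.sign(d)
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes == 1
        # large-argument Rice limit: optimum approaches F_obs
        opt = fms[np.argmin(np.abs(d))]
        assert opt == pytest.approx(fo, rel=0.02)


class TestDatasetLikelihood:
    def test_single_reflection_equals_log_p(self, cubic_cell, p1, small_state):
        refls = ReflectionSet(cubic_cell, p1, [(1, 2, 0)], [8.0])
        model = MultiStateModel([small_state], np.ones((1, 1)))
        msf, nuis = compute_msf(model, refls, 0)
        expected = -log_p_amplitude(8.0, msf.f_model_amp[0], nuis.alpha[0],
                                    nuis.beta[0], refls.epsilon[0], refls.centric[0])
        assert dataset_neg_log_likelihood(refls, msf, nuis) == pytest.approx(float(expected))

    def test_additivity_over_partition(self, toy_study):
        native = toy_study["native"]
        refls = toy_study["datasets"][0]
        msf, nuis = compute_msf(native, refls, 0)
        total = dataset_neg_log_likelihood(refls, msf, nuis)
        # partition by hand using the same nuisance
        from msxref.likelihood import log_p_amplitude as lp

        lps = lp(refls.f_obs, msf.f_model_amp, nuis.alpha_of(refls.d),
                 nuis.beta_of(refls.d), refls.epsilon, refls.centric)
        work = refls.work_mask
        half = len(refls) // 2
        part = -(lps[work & (np.arange(len(refls)) < half)].sum()
                 + lps[work & (np.arange(len(refls)) >= half)].sum())
        assert total == pytest.approx(float(part), rel=1e-12)

    def test_five_reflection_hand_sum(self, cubic_cell, p1):
        hkl = [(1, 0, 0), (1, 1, 0), (1, 1, 1), (2, 0, 0), (2, 1, 0)]
        f_obs = np.array([10.0, 20.0, 5.0, 8.0, 12.0])
        refls = ReflectionSet(cubic_cell, p1, hkl, f_obs)
        f_model = np.array([9.0, 21.0, 6.0, 8.0, 11.0])
        from msxref.forward_model import ModelStructureFactors, NuisanceParameters

        msf = ModelStructureFactors([], f_model.astype(complex),
                                    np.zeros(5, complex), f_model, np.zeros(5))
        nuis = NuisanceParameters(beta=np.array([2.0]))
        hand = -sum(float(log_p_amplitude(fo, fm, 1.0, 2.0, 1, False))
                    for fo, fm in zip(f_obs, f_model))
        assert dataset_neg_log_likelihood(refls, msf, nuis) == pytest.approx(hand, rel=1e-12)

    def test_empty_work_set_rejected(self, cubic_cell, p1):
        refls = ReflectionSet(cubic_cell, p1, [(1, 0, 0)], [5.0],
                              free_flag=np.array([True]))
        from msxref.forward_model import ModelStructureFactors, NuisanceParameters

        msf = ModelStructureFactors([], np.ones(1, complex), np.zeros(1, complex),
                                    np.ones(1), np.zeros(1))
        with pytest.raises(ValueError, match="work"):
            dataset_neg_log_likelihood(refls, msf, NuisanceParameters())


class TestJointLikelihood:
    def test_single_dataset_reduction(self, toy_study):
        native = toy_study["native"]
        ds = toy_study["datasets"]
        model1 = MultiStateModel([s.copy() for s in native.states],
                                 WeightMatrix(native.weights.w[:, :1]))
        per, total = joint_neg_log_likelihood(model1, ds[:1])
        msf, nuis = compute_msf(model1, ds[0], 0)
        assert total == pytest.approx(dataset_neg_log_likelihood(ds[0], msf, nuis))

    def test_duplicated_dataset_doubles_contribution(self, toy_study):
        native = toy_study["native"]
        ds = toy_study["datasets"][0]
        m1 = MultiStateModel([s.copy() for s in native.states],
                             WeightMatrix(native.weights.w[:, :1]))
        _, single = joint_neg_log_likelihood(m1, [ds])
        m2 = MultiStateModel([s.copy() for s in native.states],
                             WeightMatrix(np.hstack([native.weights.w[:, :1]] * 2)))
        _, double = joint_neg_log_likelihood(m2, [ds, ds])
        assert double == pytest.approx(2 * single, rel=1e-10)

    def test_componentwise_oracle(self, toy_study):
        native = toy_study["native"]
        ds = toy_study["datasets"]
        per, total = joint_neg_log_likelihood(native, ds)
        for j in (0, 1):
            msf, nuis = compute_msf(native, ds[j], j)
            assert per[j] == pytest.approx(dataset_neg_log_likelihood(ds[j], msf, nuis))
        assert total == pytest.approx(per.sum())

    def test_dataset_count_mismatch_rejected(self, toy_study):
        with pytest.raises(ValueError, match="weight columns"):
            joint_neg_log_likelihood(toy_study["native"], toy_study["datasets"][:1])

    def test_state_relabeling_symmetry(self, toy_study):
        """Swapping states together with weight rows leaves the likelihood unchanged."""
        native = toy_study["native"]
        _, total = joint_neg_log_likelihood(native, toy_study["datasets"])
        _, permuted = joint_neg_log_likelihood(native.permuted([1, 0]),
                                               toy_study["datasets"])
        assert permuted == pytest.approx(total, rel=1e-12)


class TestQuadraticApprox:
    def test_zero_at_per_reflection_optimum(self, cubic_cell, p1):
        fo, alpha, beta, eps = 10.0, 1.0, 2.0, 1
        res = minimize_scalar(
            lambda fm: -float(log_p_amplitude(fo, fm, alpha, beta, eps, False)),
            bounds=(0.1, 30), method="bounded", options={"xatol": 1e-12})
        d_at_opt = neg_log_p_derivative(fo, res.x, alpha, beta, eps, False)
        assert float(d_at_opt) == pytest.approx(0.0, abs=1e-6)

    def test_frozen_gradient_agrees_at_refresh_point(self, toy_study):
        native = toy_study["native"]
        refls = toy_study["datasets"][0]
        msf, nuis = compute_msf(native, refls, 0)
        quad_w = quadratic_gradient_weights(refls, msf, nuis)
        exact = neg_log_p_derivative(refls.f_obs, msf.f_model_amp,
                                     nuis.alpha_of(refls.d), nuis.beta_of(refls.d),
                                     refls.epsilon, refls.centric)
        work = refls.work_mask
        assert np.allclose(quad_w.gradient(msf.f_model_amp)[work], exact[work],
                           rtol=1e-12)
        assert np.all(quad_w.gradient(msf.f_model_amp)[~work] == 0.0)

    def test_curvature_tracks_exact_gradient_nearby(self, toy_study):
        native = toy_study["native"]
        refls = toy_study["datasets"][0]
        msf, nuis = compute_msf(native, refls, 0)
        quad_w = quadratic_gradient_weights(refls, msf, nuis)
        bumped = msf.f_model_amp * 1.01
        exact = neg_log_p_derivative(refls.f_obs, bumped, nuis.alpha_of(refls.d),
                                     nuis.beta_of(refls.d), refls.epsilon,
                                     refls.centric)
        work = refls.work_mask
        approx = quad_w.gradient(bumped)[work]
        scale = np.abs(exact[work]).mean()
        assert np.abs(approx - exact[work]).mean() < 0.05 * scale


class TestTotalScore:
    def test_no_datasets_reduces_to_prior(self, tiny_native):
        native = tiny_native["native"]
        params = tiny_native["params"]
        from msxref.prior_ff import potential_energy

        sb = total_score(native, [], params)
        expected = sum(potential_energy(s, params)[0] for s in native.states)
        assert sb.total == pytest.approx(expected, rel=1e-12)
        assert sb.neg_log_likelihoods.size == 0

    def test_relaxing_a_clash_lowers_score(self, tiny_native):
        native = tiny_native["native"].copy()
        params = tiny_native["params"]
        clashed = native.copy()
        # push two non-bonded atoms together in state 1
        i, j = 0, 10
        mid = 0.5 * (clashed.states[0].coords[i] + clashed.states[0].coords[j])
        clashed.states[0].coords[i] = mid - [0.9, 0, 0]
        clashed.states[0].coords[j] = mid + [0.9, 0, 0]
        s_clash = total_score(clashed, [], params)
        s_relax = total_score(native, [], params)
        assert s_relax.total < s_clash.total

    def test_componentwise_sum(self, toy_study):
        native = toy_study["native"]
        sb = total_score(native, toy_study["datasets"], toy_study["params"])
        per, total_nll = joint_neg_log_likelihood(native, toy_study["datasets"])
        from msxref.prior_ff import potential_energy

        prior = sum(potential_energy(s, toy_study["params"])[0] for s in native.states)
        assert sb.total == pytest.approx(total_nll + prior, rel=1e-12)
        assert np.allclose(sb.neg_log_likelihoods, per)
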