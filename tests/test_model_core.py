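import math
from dataclasses import replace

import numpy as np
import pytest
import scipy.stats as st

from robmeta.effect_scale import Study
from robmeta.model_core import (
    BiasComponent,
    IntegrationSettings,
    ModelSpec,
    PriorSpec,
    WeightFunctionSpec,
    conditional_effect_posterior,
    fit_model,
    ln_lik_pet_peese,
    ln_lik_random_effects,
    ln_lik_selection,
    ln_marginal_likelihood,
    omega_from_eta,
    p_value,
    prior_logpdf,
)

MU_PRIOR = PriorSpec("normal", {"loc": 0.0, "scale": 0.5})
TAU_PRIOR = PriorSpec("inverse_gamma", {"shape": 1.0, "scale": 0.075})
POINT0 = PriorSpec("point", {"loc": 0.0})


class TestPValue:
    def test_zero_statistic(self):
        s = Study(effect_z=0.0, se_z=1.0)
        assert p_value(s, "one_sided") == pytest.approx(0.5)
        assert p_value(s, "two_sided") == pytest.approx(1.0)

    def test_two_sided_at_critical_value(self):
        s = Study(effect_z=1.959964, se_z=1.0)
        assert p_value(s, "two_sided") == pytest.approx(0.05, abs=1e-6)

    def test_one_sided_symmetry(self, rng):
        for _ in range(20):
            z, se = rng.normal(), rng.uniform(0.1, 1.0)
            a = p_value(Study(effect_z=z, se_z=se), "one_sided")
            b = p_value(Study(effect_z=-z, se_z=se), "one_sided")
            assert a == pytest.approx(1.0 - b, abs=1e-12)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            Study(effect_z=0.1, se_z=-1.0)


class TestOmega:
    @pytest.mark.parametrize(
        "eta,expected",
        [((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)), ((0.5, 0.5), (1.0, 0.5))],
    )
    def test_examples(self, eta, expected):
        assert omega_from_eta(eta) == pytest.approx(expected)

    def test_monotone_and_leading_one(self, rng):
        for _ in range(2000):
            eta = rng.dirichlet(np.ones(rng.integers(2, 5)))
            om = omega_from_eta(eta)
            assert om[0] == pytest.approx(1.0)
            assert np.all(np.diff(om) <= 1e-12)

    def test_invalid_simplex(self):
        with pytest.raises(ValueError):
            omega_from_eta((0.5, 0.2))


class TestPriorLogpdf:
    def test_normal_at_zero(self):
        assert prior_logpdf(
            PriorSpec("normal", {"loc": 0, "scale": 1}), 0.0
        ) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_half_cauchy(self):
        p = PriorSpec("cauchy_plus", {"loc": 0.0, "scale": 1.0})
        assert prior_logpdf(p, -0.1) == -np.inf
        assert prior_logpdf(p, 0.0) == pytest.approx(math.log(2.0 / math.pi))

    def test_truncated_t_matches_scipy(self):
        p = PriorSpec("student_t_plus", {"loc": 0.35, "scale": 0.1, "df": 3})
        x = np.array([0.0, 0.2, 0.5, 1.0])
        base = st.t(3, loc=0.35, scale=0.1)
        expected = base.logpdf(x) - np.log1p(-base.cdf(0.0))
        assert prior_logpdf(p, x) == pytest.approx(expected)

    def test_inverse_gamma_matches_scipy(self):
        p = PriorSpec("inverse_gamma", {"shape": 1.0, "scale": 0.15})
        x = np.array([0.01, 0.1, 1.0])
        assert prior_logpdf(p, x) == pytest.approx(
            st.invgamma(1.0, scale=0.15).logpdf(x)
        )
        assert prior_logpdf(p, -0.5) == -np.inf

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PriorSpec("normal", {"loc": 0, "scale": -1})
        with pytest.raises(ValueError):
            PriorSpec("nosuch", {})


class TestLikelihoods:
    def test_single_standard_study(self):
        s = [Study(effect_z=0.0, se_z=1.0)]
        assert ln_lik_random_effects(s, 0.0, 0.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_tau_zero_is_fixed_effect(self, unbiased_studies):
        v = ln_lik_random_effects(unbiased_studies, 0.1, 0.0)
        z = np.array([s.effect_z for s in unbiased_studies])
        se = np.array([s.se_z for s in unbiased_studies])
        expected = st.norm(0.1, se).logpdf(z).sum()
        assert v == pytest.approx(expected)

    def test_equal_se_mle_at_mean(self, rng):
        z = rng.normal(0.2, 0.3, 8)
        s = [Study(effect_z=float(x), se_z=0.2) for x in z]
        best = ln_lik_random_effects(s, float(z.mean()), 0.0)
        for mu in (z.mean() - 0.1, z.mean() + 0.05, 0.0):
            assert ln_lik_random_effects(s, float(mu), 0.0) <= best + 1e-12

    def test_selection_unit_weights_equals_plain(self, rng):
        wf = WeightFunctionSpec("one_sided", (0.025, 0.05, 0.5), omega=(1, 1, 1, 1))
        for _ in range(10):
            k = int(rng.integers(1, 8))
            se = rng.uniform(0.05, 0.5, k)
            z = rng.normal(0, 0.5, k)
            s = [Study(effect_z=a, se_z=b) for a, b in zip(z, se)]
            mu, tau = rng.normal(0, 0.3), rng.uniform(0, 0.3)
            assert ln_lik_selection(s, mu, tau, wf) == pytest.approx(
                ln_lik_random_effects(s, mu, tau), abs=1e-9
            )

    def test_selection_single_study_brute_force(self):
        # one cutpoint at .05 two-sided, omega = (1, 0.5), z = 0, se = 1:
        # weight 0.5, normalizer 1 * 0.05 + 0.5 * 0.95
        wf = WeightFunctionSpec("two_sided", (0.05,), omega=(1.0, 0.5))
        s = [Study(effect_z=0.0, se_z=1.0)]
        expected = math.log(0.5) - 0.5 * math.log(2 * math.pi) - math.log(
            0.05 + 0.5 * 0.95
        )
        assert ln_lik_selection(s, 0.0, 0.0, wf) == pytest.approx(expected, abs=1e-9)

    def test_selection_weight_scaling_invariance(self, unbiased_studies):
        wf1 = WeightFunctionSpec("one_sided", (0.05,), omega=(1.0, 0.3))
        wf2 = WeightFunctionSpec("one_sided", (0.05,), omega=(0.5, 0.15))
        a = ln_lik_selection(unbiased_studies, 0.1, 0.05, wf1)
        b = ln_lik_selection(unbiased_studies, 0.1, 0.05, wf2)
        assert a == pytest.approx(b, abs=1e-9)

    def test_pet_peese_coef_zero_equals_plain(self, unbiased_studies):
        for order in (1, 2):
            assert ln_lik_pet_peese(
                unbiased_studies, 0.15, 0.1, 0.0, order
            ) == pytest.approx(ln_lik_random_effects(unbiased_studies, 0.15, 0.1))

    def test_pet_mode_residual_zero(self):
        s = [Study(effect_z=0.1 + 0.7 * 0.2, se_z=0.2)]
        v = ln_lik_pet_peese(s, 0.1, 0.0, 0.7, 1)
        assert v == pytest.approx(-math.log(0.2 * math.sqrt(2 * math.pi)))

    def test_pet_vs_peese_differ(self, unbiased_studies):
        a = ln_lik_pet_peese(unbiased_studies, 0.1, 0.0, 0.5, 1)
        b = ln_lik_pet_peese(unbiased_studies, 0.1, 0.0, 0.5, 2)
        assert a != pytest.approx(b)
        with pytest.raises(ValueError):
            ln_lik_pet_peese(unbiased_studies, 0.1, 0.0, 0.5, 3)


class TestMarginalLikelihood:
    def test_point_null_closed_form(self, unbiased_studies):
        spec = ModelSpec(POINT0, POINT0, BiasComponent("none"), 0.5)
        lnml, err = ln_marginal_likelihood(spec, unbiased_studies)
        z = np.array([s.effect_z for s in unbiased_studies])
        se = np.array([s.se_z for s in unbiased_studies])
        assert lnml == pytest.approx(st.norm(0, se).logpdf(z).sum(), abs=1e-12)
        assert err == 0.0

    def test_conjugate_normal_closed_form(self, rng, settings):
        # mu ~ N(m0, v0), tau = 0: marginal is multivariate normal
        for _ in range(20):
            k = int(rng.integers(2, 9))
            se = rng.uniform(0.05, 0.5, k)
            z = rng.normal(0.2, 0.4, k)
            studies = [Study(effect_z=a, se_z=b) for a, b in zip(z, se)]
            v0 = rng.uniform(0.05, 1.0)
            prior = PriorSpec("normal", {"loc": 0.0, "scale": math.sqrt(v0)})
            spec = ModelSpec(prior, POINT0, BiasComponent("none"), 0.5)
            lnml, _ = ln_marginal_likelihood(spec, studies, settings)
            cov = np.diag(se**2) + v0 * np.ones((k, k))
            closed = st.multivariate_normal(np.zeros(k), cov).logpdf(z)
            assert lnml == pytest.approx(closed, abs=1e-3)

    def test_mc_and_quadrature_agree_on_selection_model(self, settings):
        studies = [Study(effect_z=0.4, se_z=0.2), Study(effect_z=0.1, se_z=0.3)]
        wf = WeightFunctionSpec("one_sided", (0.05,))
        spec = ModelSpec(
            MU_PRIOR, TAU_PRIOR,
            BiasComponent("selection", weight_function=wf), 0.5,
        )
        lnml_q, err_q = ln_marginal_likelihood(spec, studies, settings)
        mc = replace(settings, method="mc", mc_draws=200000)
        lnml_mc, err_mc = ln_marginal_likelihood(
            spec, studies, mc, np.random.default_rng(3)
        )
        assert abs(lnml_q - lnml_mc) < 3 * (err_q + err_mc)

    def test_study_order_invariance(self, unbiased_studies, settings):
        wf = WeightFunctionSpec("two_sided", (0.05,))
        spec = ModelSpec(
            MU_PRIOR, TAU_PRIOR,
            BiasComponent("selection", weight_function=wf), 0.5,
        )
        a, _ = ln_marginal_likelihood(spec, unbiased_studies, settings)
        b, _ = ln_marginal_likelihood(spec, unbiased_studies[::-1], settings)
        assert a == pytest.approx(b, abs=1e-6)

    def test_empty_studies_error(self):
        spec = ModelSpec(MU_PRIOR, POINT0, BiasComponent("none"), 0.5)
        with pytest.raises(ValueError):
            ln_marginal_likelihood(spec, [])


class TestConditionalPosterior:
    def test_point_model_is_point_mass(self, unbiased_studies, settings):
        spec = ModelSpec(POINT0, TAU_PRIOR, BiasComponent("none"), 0.5)
        post = conditional_effect_posterior(spec, unbiased_studies, settings)
        assert post.point_mass_at == 0.0
        assert post.mean == 0.0

    def test_conjugate_shrinkage_mean(self, settings):
        # single study, known-variance normal model: posterior mean is the
        # precision-weighted combination of prior mean 0 and the datum
        z0, se0, v0 = 0.4, 0.2, 0.25
        spec = ModelSpec(
            PriorSpec("normal", {"loc": 0.0, "scale": math.sqrt(v0)}),
            POINT0, BiasComponent("none"), 0.5,
        )
        post = conditional_effect_posterior(
            spec, [Study(effect_z=z0, se_z=se0)], settings
        )
        expected = z0 * (v0 / (v0 + se0**2))
        assert post.mean == pytest.approx(expected, abs=1e-6)

    def test_density_integrates_to_one(self, unbiased_studies, settings):
        spec = ModelSpec(MU_PRIOR, TAU_PRIOR, BiasComponent("none"), 0.5)
        post = conditional_effect_posterior(spec, unbiased_studies, settings)
        widths = np.gradient(post.grid)
        assert float((post.density * widths).sum()) == pytest.approx(1.0, abs=1e-6)
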