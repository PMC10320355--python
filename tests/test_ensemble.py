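import math

import numpy as np
import pytest

import robmeta.ensemble as ens
from robmeta.effect_scale import Study
from robmeta.ensemble import (
    build_ensemble,
    categorize_evidence,
    fit_ensemble,
    restrict_to_bma,
)
from robmeta.model_core import FittedModel, IntegrationSettings


class TestEnsembleStructure:
    def test_has_36_members(self):
        assert len(build_ensemble()) == 36

    def test_prior_probabilities(self):
        specs = build_ensemble()
        assert sum(s.prior_prob for s in specs) == pytest.approx(1.0)
        assert sum(s.prior_prob for s in specs if s.has_effect) == pytest.approx(0.5)
        assert sum(s.prior_prob for s in specs if s.has_heterogeneity) == pytest.approx(0.5)
        assert sum(s.prior_prob for s in specs if s.has_bias) == pytest.approx(0.5)
        for s in specs:
            if s.bias.kind == "selection":
                assert s.prior_prob == pytest.approx(1 / 96)
            elif s.bias.kind in ("pet", "peese"):
                assert s.prior_prob == pytest.approx(1 / 32)
            else:
                assert s.prior_prob == pytest.approx(1 / 8)

    def test_six_selection_models_per_cell(self):
        specs = build_ensemble()
        cells = {}
        for s in specs:
            cells.setdefault((s.has_effect, s.has_heterogeneity), []).append(s)
        for members in cells.values():
            kinds = [m.bias.kind for m in members]
            assert kinds.count("selection") == 6
            assert kinds.count("pet") == 1
            assert kinds.count("peese") == 1
            assert kinds.count("none") == 1

    def test_bma_reduction(self):
        bma = restrict_to_bma(build_ensemble())
        assert len(bma) == 4
        assert all(s.prior_prob == pytest.approx(0.25) for s in bma)
        assert sum(s.prior_prob for s in bma if s.has_effect) == pytest.approx(0.5)

    def test_oosterwijk_variant(self):
        specs = build_ensemble(ens.default_effect_prior_d("oosterwijk"))
        alts = [s for s in specs if s.has_effect]
        assert all(s.effect_prior.support_bounded_below() for s in alts)


class TestCategorizeEvidence:
    @pytest.mark.parametrize(
        "bf,cat",
        [
            (11.0, "strong_alt"),
            (10.0, "moderate_alt"),
            (3.5, "moderate_alt"),
            (3.0, "undecided"),
            (1.0, "undecided"),
            (1 / 3, "undecided"),
            (0.3, "moderate_null"),
            (0.1, "moderate_null"),
            (0.05, "strong_null"),
        ],
    )
    def test_thresholds(self, bf, cat):
        assert categorize_evidence(bf) == cat

    def test_invalid(self):
        with pytest.raises(ValueError):
            categorize_evidence(0.0)


class TestFitEnsemble:
    def test_equal_marginal_likelihoods_return_priors(self, monkeypatch, settings):
        specs = build_ensemble()

        def fake_fit(spec, studies, s=None, rng=None):
            return FittedModel(
                spec, -10.0, 0.0, "closed_form", False, 0.0, 0.0,
                np.array([0.0]), np.array([1.0]), None,
                (np.array([0.0]), np.array([1.0])), {},
            )

        monkeypatch.setattr(ens, "fit_model", fake_fit)
        res = fit_ensemble(specs, [Study(effect_z=0.1, se_z=0.2)] * 3, settings)
        prior = np.array([s.prior_prob for s in specs])
        assert res.posterior_model_probs == pytest.approx(prior, abs=1e-12)
        assert res.bf_effect == pytest.approx(1.0)
        assert res.bf_heterogeneity == pytest.approx(1.0)
        assert res.bf_bias == pytest.approx(1.0)

    def test_bf_effect_odds_identity(self, small_settings, unbiased_studies):
        res = fit_ensemble(build_ensemble(), unbiased_studies, small_settings)
        p = res.p_effect
        assert res.bf_effect == pytest.approx((p / (1 - p)) / 1.0, rel=1e-9)

    def test_strong_signal_detected(self, rng, small_settings):
        # 20 tight studies at mu = 0.3: the effect-model marginal likelihood
        # dominates the null decisively (conjugate closed form), and the
        # bias-unadjusted ensemble is certain of the effect.  The full
        # ensemble stays slightly below certainty because with identical
        # standard errors the PET/PEESE shift is collinear with mu, so the
        # null+PET member can absorb part of a constant signal.
        z = rng.normal(0.3, 0.05, 20)
        se = np.full(20, 0.05)
        studies = [Study(effect_z=float(a), se_z=0.05) for a in z]
        v0 = 0.25
        import scipy.stats as st

        cov = np.diag(se**2) + v0 * np.ones((20, 20))
        ln_alt = st.multivariate_normal(np.zeros(20), cov).logpdf(z)
        ln_null = st.norm(0, se).logpdf(z).sum()
        assert ln_alt - ln_null > 10  # effect model wins by > e^10

        bma = fit_ensemble(restrict_to_bma(build_ensemble()), studies, small_settings)
        assert bma.p_effect > 0.99
        full = fit_ensemble(build_ensemble(), studies, small_settings)
        assert full.p_effect > 0.9

    def test_uninformative_study_returns_priors(self, settings):
        # a single enormous-se study carries almost no information about the
        # effect or the heterogeneity: the bias-absent reduction returns its
        # priors, and the full ensemble's effect/heterogeneity probabilities
        # stay at 1/2.  (The bias members themselves do move: an se of 150
        # is extreme data for PEESE, and a p-value of exactly 0.5 is mildly
        # informative about the selection weights.)
        studies = [Study(effect_z=0.0, se_z=150.0)]
        specs = build_ensemble()
        bma_specs = restrict_to_bma(specs)
        bma = fit_ensemble(bma_specs, studies, settings)
        for s, p in zip(bma_specs, bma.posterior_model_probs):
            assert p == pytest.approx(s.prior_prob, abs=0.01)
        res = fit_ensemble(specs, studies, settings)
        assert res.p_effect == pytest.approx(0.5, abs=0.01)
        assert res.p_heterogeneity == pytest.approx(0.5, abs=0.01)
        assert res.warnings  # k < 3 is flagged

    def test_bma_consistency_with_full_ensemble(self, unbiased_studies, settings):
        specs = build_ensemble()
        full = fit_ensemble(specs, unbiased_studies, settings)
        bma = fit_ensemble(restrict_to_bma(specs), unbiased_studies, settings)
        mask = np.array([not s.has_bias for s in specs])
        renorm = full.posterior_model_probs[mask]
        renorm = renorm / renorm.sum()
        assert bma.posterior_model_probs == pytest.approx(renorm, abs=1e-8)

    def test_averaged_quantities_are_coherent(self, unbiased_studies, small_settings):
        res = fit_ensemble(build_ensemble(), unbiased_studies, small_settings)
        lo, hi = res.averaged_ci_r
        assert -1 < lo <= math.tanh(res.averaged_effect_mean_z) <= hi < 1
        assert abs(res.averaged_effect_mean_r) <= 1
        # mixture density + point mass integrate to one
        grid, dens, atom = res.mixture_density()
        widths = np.gradient(grid)
        assert float((dens * widths).sum()) + atom == pytest.approx(1.0, abs=1e-6)

    def test_component_probabilities_partition(self, unbiased_studies, small_settings):
        specs = build_ensemble()
        res = fit_ensemble(specs, unbiased_studies, small_settings)
        p_no_eff = sum(
            p for s, p in zip(specs, res.posterior_model_probs) if not s.has_effect
        )
        assert res.p_effect + p_no_eff == pytest.approx(1.0, abs=1e-10)
        assert 0.0 <= res.p_bias <= 1.0 and 0.0 <= res.p_heterogeneity <= 1.0
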