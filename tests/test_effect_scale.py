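import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from robmeta.effect_scale import (
    Study,
    fisher_se,
    fisher_transform,
    inverse_fisher,
    rescale_prior_d_to_z,
    studies_from_frame,
    studies_to_frame,
)
from robmeta.model_core import PriorSpec


class TestFisherTransforms:
    @pytest.mark.parametrize(
        "r,z",
        [(0.0, 0.0), (0.5, 0.5 * math.log(3.0)), (-0.5, -0.5 * math.log(3.0))],
    )
    def test_known_values(self, r, z):
        assert fisher_transform(r) == pytest.approx(z, abs=1e-12)
        assert inverse_fisher(z) == pytest.approx(r, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_transform(1.0)
        with pytest.raises(ValueError):
            fisher_transform(-1.2)
        with pytest.raises(ValueError):
            inverse_fisher(float("inf"))

    @given(st.floats(-3.0, 3.0))
    @hsettings(max_examples=200, derandomize=True)
    def test_round_trip(self, z):
        assert fisher_transform(inverse_fisher(z)) == pytest.approx(z, abs=1e-12)

    def test_tanh_range_and_monotonicity(self):
        z = np.linspace(-15, 15, 101)
        r = inverse_fisher(z)
        assert np.all(np.abs(r) < 1.0)
        zz = np.linspace(-5, 5, 101)
        assert np.all(np.diff(fisher_transform(np.tanh(zz))) > 0)


class TestFisherSE:
    def test_known_values(self):
        assert fisher_se(103) == pytest.approx(0.1)
        assert fisher_se(4) == pytest.approx(1.0)

    def test_monotone_and_domain(self):
        n = np.arange(4, 500)
        assert np.all(np.diff(fisher_se(n)) < 0)
        with pytest.raises(ValueError):
            fisher_se(3)


class TestStudy:
    def test_fills_z_and_se_from_r_and_n(self):
        s = Study(effect_r=0.5, n=103)
        assert s.effect_z == pytest.approx(math.atanh(0.5))
        assert s.se_z == pytest.approx(0.1)

    def test_explicit_se_wins_over_n(self):
        s = Study(effect_z=0.2, se_z=0.3, n=103)
        assert s.se_z == 0.3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            Study(effect_r=1.5, n=10)
        with pytest.raises(ValueError):
            Study(effect_r=0.2)  # no precision information
        with pytest.raises(ValueError):
            Study(effect_z=0.2, n=3)
        with pytest.raises(ValueError):
            Study(effect_r=0.5, effect_z=0.9, n=10)  # inconsistent pair

    def test_frame_round_trip(self):
        studies = [Study(effect_r=0.3, n=40), Study(effect_z=0.1, se_z=0.2)]
        df = studies_to_frame(studies, article_id=2, meta_id=7)
        back = studies_from_frame(df)
        assert [s.effect_z for s in back] == pytest.approx(
            [s.effect_z for s in studies]
        )
        assert list(df.columns[:3]) == ["article_id", "meta_id", "study_id"]


class TestPriorRescale:
    def test_point_prior_maps_location(self):
        p = rescale_prior_d_to_z(PriorSpec("point", {"loc": 0.0}))
        assert p.family == "point" and p.params["loc"] == 0.0
        p = rescale_prior_d_to_z(PriorSpec("point", {"loc": 1.0}), "exact")
        assert p.params["loc"] == pytest.approx(math.asinh(0.5))
        p = rescale_prior_d_to_z(PriorSpec("point", {"loc": 1.0}), "linear")
        assert p.params["loc"] == pytest.approx(0.5)

    def test_exact_jacobian_at_zero(self):
        # density of the transformed prior at z=0 carries |dd/dz| = 2 cosh 0 = 2
        base = PriorSpec("normal", {"loc": 0.0, "scale": 1.0})
        p = rescale_prior_d_to_z(base, "exact")
        expected = math.log(2.0) + base.logpdf(0.0)
        assert p.logpdf(0.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", ["exact", "linear"])
    @pytest.mark.parametrize(
        "base",
        [
            PriorSpec("normal", {"loc": 0.0, "scale": 1.0}),
            PriorSpec("student_t_plus", {"loc": 0.35, "scale": 0.10, "df": 3.0}),
        ],
    )
    def test_density_integrates_to_one(self, base, mode):
        p = rescale_prior_d_to_z(base, mode)
        # integrate over the (smooth) support: truncated bases have a density
        # jump at zero that would otherwise dominate the quadrature error
        lo = 0.0 if base.support_bounded_below() else -6.0
        z = np.linspace(lo, 6, 200001)
        dens = np.exp(np.nan_to_num(p.logpdf(z), neginf=-np.inf))
        dens[~np.isfinite(dens)] = 0.0
        total = np.trapezoid(dens, z)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_linear_mode_halves_normal(self):
        p = rescale_prior_d_to_z(PriorSpec("normal", {"loc": 0.0, "scale": 1.0}), "linear")
        assert p.family == "normal"
        assert p.params["scale"] == pytest.approx(0.5)

    def test_tau_uses_linearization(self):
        base = PriorSpec("inverse_gamma", {"shape": 1.0, "scale": 0.15})
        for mode in ("exact", "linear"):
            p = rescale_prior_d_to_z(base, mode)
            assert p.family == "inverse_gamma"
            assert p.params["scale"] == pytest.approx(0.075)

    def test_small_effect_agreement(self):
        # exact d = 2 sinh z vs linear d = 2z within 1% for |z| < 0.2
        z = np.linspace(-0.2, 0.2, 101)[1:-1]
        exact = 2.0 * np.sinh(z)
        linear = 2.0 * z
        assert np.all(np.abs(exact - linear) <= 0.01 * np.abs(linear))

    def test_unsupported_family_errors(self):
        with pytest.raises(ValueError):
            rescale_prior_d_to_z(
                PriorSpec("cumulative_dirichlet", {"alpha": (1.0, 1.0)})
            )
        with pytest.raises(ValueError):
            rescale_prior_d_to_z(PriorSpec("normal", {"loc": 0, "scale": 1}), "weird")
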