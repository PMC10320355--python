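import logging

import numpy as np
import pytest

from robmeta.effect_scale import Study
from robmeta.model_core import IntegrationSettings
from robmeta.synthetic_data import DistSpec, SelectionSpec, simulate_meta_analysis

logging.getLogger("robmeta").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20230705)


@pytest.fixture
def settings():
    return IntegrationSettings()


@pytest.fixture
def small_settings():
    return IntegrationSettings.small(seed=7)


@pytest.fixture
def n_dist():
    return DistSpec(
        "lognormal", {"mean_log": np.log(60.0), "sd_log": 0.6, "minimum": 10}
    )


@pytest.fixture
def no_selection():
    return SelectionSpec("one_sided", (0.05,), (1.0, 1.0))


@pytest.fixture
def strong_selection():
    return SelectionSpec("one_sided", (0.05,), (1.0, 0.05))


def make_studies(rng, k=10, mu=0.2, tau=0.1, se_range=(0.08, 0.3)):
    """Plain unbiased studies with known truth (no selection step)."""
    se = rng.uniform(*se_range, k)
    z = rng.normal(mu, np.sqrt(tau**2 + se**2))
    return [Study(effect_z=float(a), se_z=float(b)) for a, b in zip(z, se)]


@pytest.fixture
def unbiased_studies(rng):
    return make_studies(rng, k=12)


@pytest.fixture
def selected_studies(rng, n_dist, strong_selection):
    studies, truth = simulate_meta_analysis(
        0.0, 0.0, 25, n_dist, strong_selection, rng
    )
    return studies
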