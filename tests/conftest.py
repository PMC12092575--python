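import numpy as np
import pytest

from odyn.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort (12 OED patients + 4 controls) shared by tests
    that only need structurally valid slides, not statistical power."""
    cfg = SynthConfig(n_patients=12, n_controls=4, nuclear_effect=1.5, seed=11)
    cohort, bundle = generate_cohort(cfg)
    return cfg, cohort, bundle


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from odyn.pipeline import extract_features

    _, _, bundle = small_cohort
    return extract_features(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
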