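import numpy as np
import pytest

from opsweep import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """180-record proportional cohort: fast enough for every I/O test."""
    cfg = GeneratorConfig(n=180, allocation="proportional", seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full 903-record cohort at the reference allocation."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def degenerate_config():
    """All feature SDs zero, no outcome noise, no couplings: every record
    sits exactly at its cell's mean anatomy."""
    base = GeneratorConfig()
    stats0 = {f: {c: (v[0], 0.0) for c, v in st.items()}
              for f, st in base.feature_stats.items()}
    def make(surface_form="additive"):
        return GeneratorConfig(feature_stats=stats0, sigma_fhr=0.0,
                               sigma_fa=0.0, alpha_s_go=0.0, alpha_n_ans=0.0,
                               alpha_go_po=0.0, surface_form=surface_form)
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
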