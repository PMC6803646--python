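import numpy as np
import pandas as pd
import pytest

from pleuramir import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced panel keeping the cohort's group sizes and noise levels."""
    return SyntheticConfig(n_probes=120, n_up=5, n_down=9, effect_size=6.0,
                           n_reference=6, frac_never_detected=0.3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the generator's default study conditions."""
    return generate(SyntheticConfig(seed=11))


def make_ct(values, probes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=samples)
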