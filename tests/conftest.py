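import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    """2 genes x 2 samples with known counts."""
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]],
        index=["g1", "g2"],
        columns=["s1", "s2"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted two-subtype cohort shared by mid-weight tests."""
    from nmfsubtype.simulate import SimulationSpec, simulate_counts

    spec = SimulationSpec(
        n_genes=600,
        n_samples=80,
        n_subtypes=2,
        n_signature_genes_per_subtype=40,
        signature_log2fc=2.0,
        seed=42,
    )
    counts, truth = simulate_counts(spec)
    return spec, counts, truth
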