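import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from armscan import segmentation as seg
from armscan import synthetic as syn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mini_bundle():
    """Seven families x 4 taxa: small but structurally complete."""
    cfg = syn.default_config(taxa_per_family=4)
    return syn.generate_family(cfg, seed=31)


@pytest.fixture(scope="session")
def mini_annotations(mini_bundle):
    anns = seg.project_core(
        mini_bundle.alignment, mini_bundle.reference_id, mini_bundle.ref_core
    )
    return {a.protein_id: a for a in anns}


@pytest.fixture(scope="session")
def study_bundle():
    """The full study conditions: 7 families x 50 taxa (shared across tests)."""
    cfg = syn.default_config(taxa_per_family=50)
    return syn.generate_family(cfg, seed=2026)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
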