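import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enhlink.catalog import build_catalog, classify_by_binding, read_enhancer_bed
from enhlink.io import read_bed
from enhlink.simulate import SyntheticConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Default synthetic genome with noise_sd=0 (shared, read-only)."""
    cfg = SyntheticConfig(seed=11, noise_sd=0.0)
    out = tmp_path_factory.mktemp("bundle_noiseless")
    paths, truth = generate(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default synthetic genome with default noise (shared, read-only)."""
    cfg = SyntheticConfig(seed=12)
    out = tmp_path_factory.mktemp("bundle_noisy")
    paths, truth = generate(cfg, out)
    return cfg, paths, truth


def load_classified(paths):
    """Catalog + bound/unbound partition from a generated bundle."""
    cage = read_enhancer_bed(paths["cage"], "CAGE")
    groseq = read_enhancer_bed(paths["groseq"], "GROseq")
    enhancers, summary = build_catalog(cage, groseq)
    bound, unbound = classify_by_binding(enhancers, read_bed(paths["peaks"]))
    return enhancers, summary, bound, unbound


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
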