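import numpy as np
import pytest

from spatialrisk.synthdata import SimConfig, generate_contacts, generate_eqtl_table, generate_reference


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_cases=150,
        n_controls=150,
        n_snps=60,
        n_genes=24,
        n_tissues=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_contacts(small_config, small_reference):
    return generate_contacts(small_reference, small_config)


@pytest.fixture(scope="session")
def small_eqtls(small_config, small_reference):
    return generate_eqtl_table(small_reference, small_config)


def random_feature_matrix(n=80, p=6, seed=0, effect=0.0):
    """Gaussian feature matrix with balanced labels and optional mean shift."""
    from spatialrisk.features import FeatureKey, FeatureMatrix

    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == 1, 0] += effect
    keys = [FeatureKey(kind="snp", snp_id=f"rs{i:03d}") for i in range(p)]
    return FeatureMatrix([f"s{i:04d}" for i in range(n)], keys, X, y)
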