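import numpy as np
import pytest

from nanocorona.io_formats import ProteinRecord
from nanocorona.sequence_features import feature_table, scale_features
from nanocorona.synthetic_data import ScenarioConfig, gen_proteins


@pytest.fixture(scope="session")
def small_scenario():
    """50 proteins per class with the default planted composition signal."""
    cfg = ScenarioConfig(seed=11, n_per_class=50, length_range=(60, 150))
    proteins, labels = gen_proteins(cfg)
    return cfg, proteins, labels


@pytest.fixture(scope="session")
def small_scaled_features(small_scenario):
    """Scaled feature table + labels for the small planted scenario."""
    _, proteins, labels = small_scenario
    table = feature_table(proteins).drop(columns=["exposure_source"])
    scaled, fit = scale_features(table)
    return scaled, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequences(rng, n, min_len=10, max_len=60):
    """Random standard-residue sequences for oracle comparisons."""
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out
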