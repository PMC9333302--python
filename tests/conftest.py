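import numpy as np
import pytest

from reproscore import DiscoveryConfig, LabeledDataset, SyntheticSpec, generate


@pytest.fixture
def cfg():
    """Canonical discovery operator: pooled t, alpha = 0.05, BH."""
    return DiscoveryConfig()


@pytest.fixture
def tiny_dataset():
    """6 subjects x 3 features, 3 per class, hand-enterable values."""
    values = np.array(
        [
            [1.0, 5.0, 0.3],
            [2.0, 6.0, 0.1],
            [3.0, 7.0, 0.2],
            [1.5, 1.0, 0.25],
            [2.5, 2.0, 0.15],
            [3.5, 3.0, 0.35],
        ]
    )
    return LabeledDataset(
        values,
        ["case", "case", "case", "ctrl", "ctrl", "ctrl"],
        feature_ids=["g1", "g2", "g3"],
        positive_label="case",
    )


@pytest.fixture
def signal_dataset():
    """Moderate-size dataset with 20 strongly shifted features out of 200."""
    spec = SyntheticSpec(
        n_plus=100, n_minus=100, r=200, n_true=20, effect=1.0, seed=7
    )
    return generate(spec)
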