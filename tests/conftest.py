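import numpy as np
import pandas as pd
import pytest

from hbpkit.synth import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def separable_table():
    """Linearly separable numeric feature table: 2 informative + 8 noise columns."""
    rng = np.random.default_rng(1)
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 10))
    X[:, 0] += 4.0 * y  # wide margin on two coordinates
    X[:, 1] -= 4.0 * y
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)],
                         index=pd.Index([f"s{i}" for i in range(n)], name="id"))
    table["label"] = y
    table.attrs["feature_version"] = "test-sep-v1"
    return table


@pytest.fixture(scope="session")
def small_synth_dataset():
    """Tiny high-signal synthetic sequence dataset (20 per class)."""
    return generate_dataset(
        SynthSpec(n_per_class=20, length_range=(50, 120), effect_size=1.0, seed=11)
    )
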