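import numpy as np
import pandas as pd
import pytest

from olfnet import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    """Null configuration (no planted effects), small cohort."""
    return syn.SimulationSpec(n_subjects=40, seed=11, n_regions=8,
                              n_genes=120, n_modules=3, module_size=25)


@pytest.fixture(scope="session")
def small_traits(small_spec):
    return syn.generate_traits(small_spec)


@pytest.fixture(scope="session")
def small_trials(small_spec, small_traits):
    return syn.generate_behavior(small_traits, small_spec)


@pytest.fixture(scope="session")
def balanced_design():
    """Fully balanced 2x2x2 design, 5 replicates per cell."""
    rows = []
    i = 0
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            for c in ("c1", "c2"):
                for _ in range(5):
                    i += 1
                    rows.append((f"S{i:03d}", a, b, c))
    return pd.DataFrame(rows, columns=["subject_id", "fa", "fb", "fc"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
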