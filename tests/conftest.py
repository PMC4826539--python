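import numpy as np
import pytest

import glucotime as gt

SEED = 20131101  # study window start used as an arbitrary fixed seed


@pytest.fixture(scope="session")
def adherent_panel():
    """Small adherent panel: 2 wards x 10 days, published median parameters."""
    spec = gt.GeneratorSpec(n_wards=2, n_days=10, seed=SEED % 2**31)
    panel, truth = gt.generate_panel(spec)
    return panel, truth


@pytest.fixture(scope="session")
def table2_ward():
    """One full-length adherent ward (61 days, ~80 measurements/day)."""
    spec = gt.GeneratorSpec(n_wards=1, n_days=61, daily_n=(75, 85), seed=11)
    panel, truth = gt.generate_panel(spec)
    return panel, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED % 2**31)
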