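import numpy as np
import pandas as pd
import pytest

import rnevo as rn


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic study (~20 years, ~300 females)."""
    cfg = rn.SimulationConfig(n_founders=30, n_years=20, seed=42)
    return rn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def nuclear_pedigree():
    """Two founder pairs, full sibs, half sibs: all relationships known."""
    rows = [
        # id, dam, sire, cohort, sex
        ("d1", None, None, 2000, "F"),
        ("s1", None, None, 2000, "M"),
        ("d2", None, None, 2000, "F"),
        ("c1", "d1", "s1", 2001, "F"),
        ("c2", "d1", "s1", 2001, "M"),
        ("h1", "d2", "s1", 2001, "F"),
    ]
    return rn.Pedigree(
        pd.DataFrame(rows, columns=["id", "dam", "sire", "cohort", "sex"])
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
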