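import numpy as np
import pytest

import twinscales as ts


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared by read-only tests."""
    cfg = ts.SimConfig(seed=11)
    resp, ped, truth = ts.simulate_cohort(cfg)
    return cfg, resp, ped, truth


@pytest.fixture(scope="session")
def unrelated_cohort_2000():
    """2000 unrelated respondents on a clean 10-item bank (single trait)."""
    bank = [ts.ItemSpec(item_id=i, a=1.8, b1=-1.2 + 0.3 * i, b2=0.0 + 0.3 * i)
            for i in range(1, 11)]
    cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=2000,
                         item_bank=bank, seed=21)
    resp, ped, truth = ts.simulate_cohort(cfg)
    return bank, resp, ped, truth
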