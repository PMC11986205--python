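import numpy as np
import pytest

import asymadstrat as a


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced size, with ground truth."""
    return a.generate_cohort(a.default_config(
        n_control=60, n_asymad=60, n_ad=60, seed=1))


@pytest.fixture(scope="session")
def panel_result(small_cohort):
    table, _ = small_cohort
    return a.select_panel(table, a.SelectionConfig(seed=1))


@pytest.fixture(scope="session")
def split_ids(small_cohort):
    table, _ = small_cohort
    from asymadstrat.panel import split_train_test
    return split_train_test(table, a.SelectionConfig(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
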