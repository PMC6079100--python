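import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sortscreen import simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_library():
    return simulate.make_guide_library(20, 6, 3, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_library):
    params = simulate.ScreenSimParams(
        n_genes=20, sequencing_depth=200_000, seed=12
    )
    counts, truth = simulate.simulate_sort_screen(
        small_library, {"gene00000": 3.0}, params
    )
    return counts, truth


@pytest.fixture(scope="session")
def lfq_null():
    return simulate.simulate_lfq_experiment(400, 0, seed=21)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.simulate_cohort(200, n_genes=500, trps1_set_size=40,
                                    yap_set_size=40, seed=31)
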