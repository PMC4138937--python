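import numpy as np
import pytest

import restdecode as rd


@pytest.fixture(scope="session")
def table1():
    return rd.table1_template()


@pytest.fixture(scope="session")
def d160():
    return rd.dosenbach160_template()


@pytest.fixture(scope="session")
def small_cohort_tables(d160):
    """12-subject cohort with the default planted effect, plus its config."""
    cfg = rd.SimulationConfig(n_subjects=12, seed=7)
    cohort = rd.simulate_cohort(cfg, d160)
    tables = rd.falff_feature_table(cohort, d160)
    return cfg, tables


@pytest.fixture(scope="session")
def null_cohort_tables(d160):
    """12-subject cohort with no condition effect."""
    cfg = rd.SimulationConfig(n_subjects=12, seed=11, effect_size=0.0)
    cohort = rd.simulate_cohort(cfg, d160)
    tables = rd.falff_feature_table(cohort, d160)
    return cfg, tables


def on_bin_sinusoid(k: int, n: int = 230, tr: float = 2.0, amp: float = 1.0,
                    phase: float = 0.3) -> np.ndarray:
    """Pure tone exactly on DFT bin k of an n-point series."""
    t = np.arange(n) * tr
    return amp * np.sin(2 * np.pi * (k / (n * tr)) * t + phase)
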