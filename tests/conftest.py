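import numpy as np
import pytest

from dsdseq import gcnorm
from dsdseq.simulate import SimConfig, simulate_cohort_45, simulate_depth, toy_panel


@pytest.fixture(scope="session")
def panel_and_windows():
    return toy_panel()


@pytest.fixture(scope="session")
def cohort45():
    """The 45-sample validation cohort, simulated at defaults and GC-corrected."""
    dm, truth = simulate_cohort_45(seed=1)
    gcnorm.correct_matrix(dm)
    return dm, truth


@pytest.fixture(scope="session")
def clean_batch(panel_and_windows):
    """A 10-sample XY batch with no CNVs, GC-corrected."""
    panel, windows = panel_and_windows
    cfg = SimConfig(seed=7, karyotypes={f"N{i:02d}": "XY" for i in range(10)},
                    panel=panel, windows=windows)
    dm, truth = simulate_depth(cfg)
    gcnorm.correct_matrix(dm)
    return dm, truth
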