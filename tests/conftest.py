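import numpy as np
import pandas as pd
import pytest

from facevoice.design import TrialDesign, build_grid, enumerate_pairs


@pytest.fixture(scope="session")
def grid3():
    """The 3x3 reduced grid (feminine / neutral / masculine per modality)."""
    return build_grid(3, 3)


@pytest.fixture(scope="session")
def full_grid():
    """The full 18x19 psychophysics morph lattice."""
    return build_grid(18, 19)


def exhaustive_design(grid, n_repeats=1):
    """Every unordered pair presented ``n_repeats`` times, fixed order."""
    pairs = enumerate_pairs(grid)
    rows = [(*s1, *s2) for _ in range(n_repeats) for s1, s2 in pairs]
    df = pd.DataFrame(rows, columns=["face1", "voice1", "face2", "voice2"])
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "session", 0)
    return TrialDesign(grid, df, 1, len(df), None)


@pytest.fixture(scope="session")
def design3x50(grid3):
    """All 36 pairs of the 3x3 grid, 50 repeats each."""
    return exhaustive_design(grid3, n_repeats=50)
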