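import numpy as np
import pandas as pd
import pytest

from trips.timescale import Stage, Timescale, load_default_timescale


@pytest.fixture(scope="session")
def mesozoic():
    return load_default_timescale()


@pytest.fixture
def two_stage_ts():
    """Minimal timescale: two contiguous stages of 2 and 6 Myr."""
    return Timescale([Stage("Olderian", 10.0, 8.0), Stage("Youngian", 8.0, 2.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(counts: dict[str, list[int]], stages: list[str], rank="species"):
    """Build a CountMatrix from {taxon: per-stage counts}."""
    from trips.occurrences import CountMatrix

    df = pd.DataFrame.from_dict(counts, orient="index", columns=stages).astype(int)
    return CountMatrix(df, rank=rank)
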