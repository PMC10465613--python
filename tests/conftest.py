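import numpy as np
import pandas as pd
import pytest

from temeth import (ModCallSet, build_genome, default_config,
                    default_trajectories)


@pytest.fixture(scope="session")
def world():
    """The packaged default world (seed 1729)."""
    return build_genome(default_config())


@pytest.fixture(scope="session")
def trajectories():
    return default_trajectories()


def make_callset(rows):
    """ModCallSet from (chrom, pos, strand) or full 6-tuples."""
    full = [(r if len(r) == 6 else (*r, 30, 50, 0.1)) for r in rows]
    if not full:
        return ModCallSet.empty()
    return ModCallSet(pd.DataFrame(full, columns=list(ModCallSet.COLUMNS)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
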