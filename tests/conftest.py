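import numpy as np
import pandas as pd
import pytest

import symbiostrain as st


@pytest.fixture(scope="session")
def strain_pair():
    """One 10-kb scaffold pair diverged at 0.65 substitutions/100 bp."""
    return st.gen_strain_pair(st.StrainPairModel(1, 10_000, 0.65, seed=11))


@pytest.fixture(scope="session")
def multi_scaffold_pair():
    """Three 20-kb scaffolds, used for window statistics tests."""
    return st.gen_strain_pair(st.StrainPairModel(3, 20_000, 0.65, seed=12))


@pytest.fixture(scope="session")
def mixed_pools(multi_scaffold_pair):
    """Resistant pool fixed for N, susceptible pool at S fraction 0.47."""
    sites = multi_scaffold_pair.sites
    res = st.simulate_pool_pileup(
        sites, st.PoolSpec("resistant", 0.0, 96.0, seed=21)
    )
    sus = st.simulate_pool_pileup(
        sites, st.PoolSpec("susceptible", 0.47, 40.0, seed=22)
    )
    return res, sus


def make_pileup(scaffold, positions, depth, s_count):
    n = len(positions)
    return pd.DataFrame(
        {
            "scaffold": [scaffold] * n,
            "pos": positions,
            "depth": np.broadcast_to(depth, n).copy(),
            "s_count": np.broadcast_to(s_count, n).copy(),
        }
    )
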