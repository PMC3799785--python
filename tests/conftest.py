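import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finswim import synthdata
from finswim.synthdata import SyntheticConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def star_tree():
    """Equal-branch star phylogeny on 12 tips."""
    newick = "(" + ",".join(f"s{i}:1.0" for i in range(12)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def small_tree():
    """Hand-built 3-tip tree ((A:1,B:1):1,C:2); with known VCV and contrasts."""
    return dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")


@pytest.fixture
def mpf_dataset(rng):
    """A 55-species MPF group with its generating tree and truth record."""
    tree = synthdata.simulate_tree(55, 1.0, rng=rng)
    records, truth = synthdata.simulate_records(SyntheticConfig(n=55), tree=tree, rng=rng)
    return records, tree, truth


@pytest.fixture
def bcf_dataset(rng):
    config = SyntheticConfig(
        n=29, gait="BCF", f_mean=2.6, beta=(-0.15, -0.3, 0.5, 0.2)
    )
    records, truth = synthdata.simulate_records(config, rng=rng)
    return records, truth
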