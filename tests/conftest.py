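import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from miace.data_io import Bag, BagSet, BandAxis
from miace import synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bagset():
    """Two crowns, five bands, hand-set labels."""
    axis = BandAxis([400.0, 500.0, 600.0, 700.0, 800.0])
    bags = [
        Bag("c1", np.array([[0.1, 0.2, 0.3, 0.4, 0.5], [0.2, 0.3, 0.4, 0.5, 0.6]]), "PI", "PIPA"),
        Bag("c2", np.array([[0.5, 0.4, 0.3, 0.2, 0.1]]), "QU", "QULA"),
    ]
    return BagSet(bags, axis)


@pytest.fixture(scope="session")
def separable_bagset():
    """Four well-separated species classes; the easy regime where every
    pairwise problem is cleanly solvable."""
    cfg = synthetic.make_config(
        n_classes=4, n_bands=50, seed=11, bags_per_class=10, instances_per_bag=(8, 15)
    )
    bagset, truth = synthetic.generate(cfg)
    return cfg, bagset, truth


@pytest.fixture(scope="session")
def hierarchical_bagset():
    """Two genera (one single-species, one with three species), separable."""
    cfg = synthetic.make_config(
        n_classes=4, n_bands=50, seed=7, bags_per_class=10, instances_per_bag=(8, 15)
    )
    genus_map = {"AC": ["ACRU"], "PI": ["PIEL", "PIPA", "PITA"]}
    tcfg = synthetic.two_level_config(cfg, genus_map, within_genus_similarity=0.4)
    bagset, truth = synthetic.generate(tcfg)
    return tcfg, bagset, truth
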