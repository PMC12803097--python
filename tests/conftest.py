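import numpy as np
import pytest

from paleorealms.core import CladeDataset, ModelParams, RangeState, RealmSet, parse_newick
from paleorealms.dmm import StratifiedDMM
from paleorealms.simulate import SimConfig, sim_tree


@pytest.fixture
def realms2():
    return RealmSet(("A", "B"))


@pytest.fixture
def realms3():
    return RealmSet(("A", "B", "C"))


@pytest.fixture
def marine_realms():
    return RealmSet.marine()


@pytest.fixture
def uniform_dmm2(realms2):
    return StratifiedDMM.uniform(realms2)


@pytest.fixture
def uniform_dmm3(realms3):
    return StratifiedDMM.uniform(realms3)


@pytest.fixture
def stratified_dmm3(realms3):
    """Two-epoch stack with contrasting multipliers to exercise time splits."""
    M_recent = np.ones((3, 3))
    M_old = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.7], [0.2, 0.7, 1.0]])
    return StratifiedDMM(realms3, [2.0, 400.0], [M_recent, M_old])


@pytest.fixture
def cherry_clade(realms2):
    """Two tips, both in realm A, 1-Myr branches."""
    tree = parse_newick("(a:1,b:1);")
    return CladeDataset(tree, {"a": RangeState(1, 2), "b": RangeState(1, 2)})


@pytest.fixture
def small_clade(realms3, uniform_dmm3):
    """Simulated 12-tip clade over 3 realms with known parameters."""
    from paleorealms.simulate import sim_ranges

    cfg = SimConfig(seed=11, n_tips=12, n_realms=3, params=ModelParams(d=0.08, e=0.02))
    tree = sim_tree(cfg)
    ranges, log = sim_ranges(tree, uniform_dmm3, cfg)
    return CladeDataset(tree, ranges), log, cfg
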