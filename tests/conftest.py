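import numpy as np
import pytest

import radfate as rf
from radfate.p53net import build_network


@pytest.fixture(scope="session")
def network():
    net = build_network()
    net.basal_state()
    return net


@pytest.fixture(scope="session")
def damage_2gy():
    return rf.generate_damage(2.0, seed=11)


@pytest.fixture()
def single_dsb_factory():
    def make(pathway, coord=(0.0, 0.0, 0.0)):
        rec = rf.DSBRecord(
            id=0, coord=np.asarray(coord, dtype=float),
            complexity=rf.Complexity.SIMPLE, chromatin=rf.Chromatin.EC,
            pathway=pathway,
        )
        return rf.DamageSet([rec], nucleus_radius=5000.0)
    return make
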