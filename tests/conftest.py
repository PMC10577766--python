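import pytest

import sesnet as sn


@pytest.fixture
def sphere_mol():
    """One carbon-like atom (r = 1.7 Å) at the origin."""
    return sn.generate_synthetic("single", 1, radius=1.7)


@pytest.fixture
def diatomic_mol():
    """Two 1.7 Å atoms separated by 3.4 Å: a probe-inaccessible crevice."""
    return sn.generate_synthetic("diatomic", 2, separation=3.4, radius=1.7)


@pytest.fixture
def cluster_mol():
    """A small bonded cluster with reentrant geometry."""
    return sn.generate_synthetic("cluster", 12, seed=7)


@pytest.fixture
def cluster_field(cluster_mol):
    """Oracle-labeled field of the small cluster at 0.5 Å spacing."""
    grid = sn.make_grid(cluster_mol, 0.5)
    return sn.label_level_set(cluster_mol, grid, sn.ProbeParams(1.4))
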