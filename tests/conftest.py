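import numpy as np
import pytest

from dgnet import config, morphology, network


@pytest.fixture(scope="session")
def pools():
    """Default synthetic morphology pools shared across the suite."""
    return network.default_pools(seed=7)


@pytest.fixture(scope="session")
def desk_cfg():
    return config.desk_scale()


@pytest.fixture()
def chain_tree():
    """Soma + straight apical chain with segments 20 µm and 30 µm."""
    return morphology.MorphTree(
        structure=np.array([1, 4, 4]),
        xyz=np.array([[0, 0, 0], [0, 20, 0], [0, 50, 0]], dtype=float),
        radius=np.array([6.0, 1.0, 0.8]),
        parent=np.array([-1, 0, 1]),
        name="chain", population="mature",
    )


@pytest.fixture()
def y_tree():
    """Soma with a stem branching into two arms of total extents 120/180 µm."""
    return morphology.MorphTree(
        structure=np.array([1, 4, 4, 4, 4, 4]),
        xyz=np.array(
            [[0, 0, 0], [0, 60, 0], [40, 120, 0], [0, 120, 0], [0, 180, 0], [0, 120 + 60, 40]],
            dtype=float,
        ),
        radius=np.array([6.0, 1.2, 0.8, 0.8, 0.6, 0.6]),
        # stem 0-1 (60), arm A: 1->2 (~72 -> 132 total), arm B: 1->3->4
        parent=np.array([-1, 0, 1, 1, 3, 4]),
        name="ytree", population="mature",
    )


def write_swc(path, rows):
    with open(path, "w") as fh:
        fh.write("# test fixture\n")
        for r in rows:
            fh.write(" ".join(str(x) for x in r) + "\n")
    return path
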