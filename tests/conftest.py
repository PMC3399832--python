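import numpy as np
import pytest

from loopdyn.structure_io import CAStructure, Residue
from loopdyn.synthetic_data import make_chain


@pytest.fixture
def chain5():
    return make_chain(5, "extended")


@pytest.fixture
def helix5():
    return make_chain(5, "helix")


@pytest.fixture
def tripeptide():
    """Gly-Arg-Cys all-atom-ish fixture (key side-chain atoms only)."""
    def res(chain, rid, name, atoms):
        names = [a for a, _ in atoms]
        coords = np.array([xyz for _, xyz in atoms], dtype=float)
        elements = [a[:1] for a in names]
        return Residue(chain, rid, "", name, names, elements, coords)

    gly = res("A", 1, "GLY", [
        ("N", (0.0, 0.0, 0.0)), ("CA", (1.5, 0.0, 0.0)),
        ("C", (2.2, 1.3, 0.0)), ("O", (1.6, 2.4, 0.0)),
    ])
    arg = res("A", 2, "ARG", [
        ("N", (3.5, 1.3, 0.0)), ("CA", (4.4, 2.4, 0.0)),
        ("C", (5.8, 2.0, 0.5)), ("O", (6.1, 0.8, 0.6)),
        ("CB", (4.4, 3.5, 1.1)), ("CG", (5.0, 4.8, 0.7)),
        ("CD", (5.0, 5.9, 1.7)), ("NE", (5.6, 7.1, 1.2)),
        ("CZ", (5.6, 8.3, 1.8)), ("NH1", (5.0, 8.4, 3.0)),
        ("NH2", (6.2, 9.3, 1.2)),
    ])
    cys = res("A", 3, "CYS", [
        ("N", (6.7, 3.0, 0.8)), ("CA", (8.1, 2.9, 1.2)),
        ("C", (8.9, 4.2, 1.1)), ("O", (8.4, 5.3, 1.3)),
        ("CB", (8.8, 1.8, 0.4)), ("SG", (10.5, 1.5, 0.9)),
    ])
    return CAStructure([gly, arg, cys], label="GRC")


def two_bead_network(d=3.8, k=40.0):
    from loopdyn.cg_ensembles import ElasticNetwork
    coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    return ElasticNetwork(coords, np.array([[0, 1]]), np.array([d]),
                          np.array([k]))
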