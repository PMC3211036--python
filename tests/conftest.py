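import math

import pytest
from hypothesis import settings

from iset.descriptor import compute_descriptor, load_sidecar
from iset.molgraph import parse_structure
from iset.paperdata import data_path, load_table1, load_table3

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hexanone_graph():
    return parse_structure("CCC(=O)CCC", name="3-hexanone")


@pytest.fixture(scope="session")
def hexanone_sidecar():
    return load_sidecar(data_path("hexan3one.state.yaml"))


@pytest.fixture(scope="session")
def hexanone_breakdown(hexanone_graph, hexanone_sidecar):
    return compute_descriptor(hexanone_graph, hexanone_sidecar)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


def brute_iset(elements, bonds, eff):
    """Edge-based oracle for the descriptor aggregation.

    Writes the double sum as one linear pass over atoms plus, for every
    bond, the base-10 logs of both endpoint values — an algebraically
    equivalent but structurally different evaluation from the per-atom
    neighbour loop in the implementation.
    """
    total = sum(eff[i] for i in range(1, len(elements) + 1))
    for pair in bonds:
        a, b = sorted(pair)
        total += math.log10(eff[a]) + math.log10(eff[b])
    return total
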