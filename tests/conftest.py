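import numpy as np
import pytest

import physcent as pc
from physcent.physarum import PhysarumParams

LINEAR = PhysarumParams(f_kind="linear")


@pytest.fixture
def path3():
    return pc.fixture("path3")


@pytest.fixture
def path4():
    return pc.fixture("path4")


@pytest.fixture
def star4():
    return pc.fixture("star4")


@pytest.fixture
def cycle4():
    return pc.fixture("cycle4")


@pytest.fixture
def tworoute():
    return pc.fixture("tworoute")


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny seeded cohort shared by group-statistics tests."""
    base = pc.generate_connectome(
        pc.ConnectomeSpec(n=16, density=0.3, n_modules=2, seed=42)
    )
    mats = pc.generate_cohort(
        base, n_subjects=6, weight_noise_sd=0.1, topology_rewire_p=0.05, seed=42
    )
    return pc.build_cohort(mats)


def random_connected(rng: np.random.Generator, n_max: int = 9, weights="uniform"):
    """Random connected weighted ConnectivityMatrix for property tests."""
    import networkx as nx

    while True:
        n = int(rng.integers(4, n_max + 1))
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
        if not nx.is_connected(G):
            continue
        w = np.zeros((n, n))
        for a, b in G.edges():
            if weights == "uniform":
                val = float(rng.uniform(0.1, 1.0))
            else:
                val = float(rng.choice([0.25, 0.5, 1.0]))
            w[a, b] = w[b, a] = val
        return pc.ConnectivityMatrix(w)
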