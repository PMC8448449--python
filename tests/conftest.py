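import numpy as np
import pytest

from trapchip.population import ClonePopulationSpec, sample_clone_population
from trapchip.render import SceneSpec, render_experiment


@pytest.fixture(scope="session")
def scene():
    return SceneSpec()


@pytest.fixture(scope="session")
def clone_table():
    return sample_clone_population(ClonePopulationSpec(n_clones=20, seed=2))


@pytest.fixture(scope="session")
def clean_bundle(scene, clone_table):
    """One noise-free, unrotated field of view over 5 days, all channels."""
    return render_experiment(clone_table, scene, seed=5)


def brute_force_flows(network):
    """Independent dense Kirchhoff solve: enumerate one conservation
    equation per interior node plus the two boundary constraints, solve by
    least squares, and return (pressures, edge flows)."""
    nodes = list(network.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(u, v, k, d["conductance"])
             for u, v, k, d in network.graph.edges(keys=True, data=True)]
    rows, rhs = [], []
    for node in nodes:
        if node in network.boundary:
            row = np.zeros(len(nodes))
            row[idx[node]] = 1.0
            rows.append(row)
            rhs.append(network.boundary[node])
        else:
            row = np.zeros(len(nodes))
            for u, v, _, g in edges:
                if u == node:
                    row[idx[u]] += g
                    row[idx[v]] -= g
                elif v == node:
                    row[idx[v]] += g
                    row[idx[u]] -= g
            rows.append(row)
            rhs.append(0.0)
    p, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    pressures = {n: p[idx[n]] for n in nodes}
    flows = {(u, v, k): g * (pressures[u] - pressures[v]) for u, v, k, g in edges}
    return pressures, flows


def random_ladder_spec(rng, max_traps=10, occupy=True):
    from trapchip.ladder import LadderSpec
    n = int(rng.integers(1, max_traps + 1))
    occ = frozenset()
    if occupy and n > 1 and rng.random() < 0.5:
        k = int(rng.integers(0, n))
        occ = frozenset(int(i) for i in rng.choice(n, size=k, replace=False))
    return LadderSpec(
        n_traps=n,
        R_A=float(rng.uniform(0.1, 10.0)),
        R_S=float(rng.uniform(0.1, 10.0)),
        R_rung=float(rng.uniform(0.02, 2.0)),
        kappa=float(rng.uniform(1.0, 300.0)),
        occupied=occ,
    )
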