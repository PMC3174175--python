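import numpy as np
import pytest

from etmc import (
    ImpactConfig,
    apply_condition,
    build_impact_matrix,
    carbon_starvation_fixture,
    two_gene_fixture,
    uniform_chain,
)


@pytest.fixture(scope="session")
def two_gene():
    etg, configs = two_gene_fixture()
    return etg, configs


@pytest.fixture(scope="session")
def two_gene_impact_x(two_gene):
    etg, configs = two_gene
    return build_impact_matrix(etg, configs["x"])


@pytest.fixture(scope="session")
def carbon():
    etg, configs = carbon_starvation_fixture()
    return etg, configs


@pytest.fixture(scope="session")
def carbon_starved(carbon):
    etg, configs = carbon
    sub = apply_condition(etg, "starvation")
    impacts = {
        gene: build_impact_matrix(sub, ImpactConfig(protein=gene))
        for gene in configs
    }
    return sub, impacts


def brute_force_moment(P, I, v0, n, power=1):
    """Exhaustive path enumeration: E[(product of impacts along path)^power].

    Independent oracle for exact_mean / second moments: walks every length-n
    path, weighting by start probability times transition probabilities.
    """
    nev = P.values.shape[0]
    total = 0.0
    stack = [(i, float(v0[i]), 1.0) for i in range(nev) if v0[i] > 0]
    if n == 0:
        return float(sum(w for _, w, _ in stack))
    for _ in range(n):
        nxt = []
        for (i, w, cost) in stack:
            for j in range(nev):
                p = P.values[i, j]
                if p > 0:
                    nxt.append((j, w * p, cost * I.values[i, j]))
        stack = nxt
    for (_, w, cost) in stack:
        total += w * cost**power
    return total
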