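"""Shared fixtures: hand-built micro-ARGs and small simulations."""

import numpy as np
import pandas as pd
import pytest

from vgdate.arg_tables import ArgTables


def make_tables(nodes, edges, sites=None, mutations=None, **kw):
    """Build ArgTables from lists of tuples (convenience for fixtures)."""
    ndf = pd.DataFrame(nodes, columns=["id", "time", "is_sample",
                                       "individual"])
    edf = pd.DataFrame(edges, columns=["left", "right", "parent", "child"])
    sdf = (pd.DataFrame(sites, columns=["id", "position", "ancestral_state"])
           if sites else None)
    mdf = (pd.DataFrame(mutations,
                        columns=["id", "site", "node", "derived_state",
                                 "unphased_individual"])
           if mutations else None)
    return ArgTables.from_frames(ndf, edf, sdf, mdf, **kw)


@pytest.fixture
def cherry():
    """Two samples coalescing in one root; two mutations on one edge,
    one on the other."""
    nodes = [(0, 0.0, 1, -1), (1, 0.0, 1, -1), (2, np.nan, 0, -1)]
    edges = [(0.0, 100.0, 2, 0), (0.0, 100.0, 2, 1)]
    sites = [(0, 10.0, "0"), (1, 20.0, "0"), (2, 30.0, "0")]
    muts = [(0, 0, 0, "1", -1), (1, 1, 0, "1", -1), (2, 2, 1, "1", -1)]
    return make_tables(nodes, edges, sites, muts)


@pytest.fixture
def star5():
    """Five sample edges meeting in a single root."""
    nodes = [(i, 0.0, 1, -1) for i in range(5)] + [(5, np.nan, 0, -1)]
    edges = [(0.0, 200.0, 5, i) for i in range(5)]
    ys = [2, 0, 1, 3, 0]
    sites, muts, k = [], [], 0
    for child, y in enumerate(ys):
        for _ in range(y):
            sites.append((k, 1.0 + k, "0"))
            muts.append((k, k, child, "1", -1))
            k += 1
    return make_tables(nodes, edges, sites, muts)


@pytest.fixture
def chain():
    """sample 0 -> node 1 -> node 2 (root); two counts on the lower
    edge, one on the upper."""
    nodes = [(0, 0.0, 1, -1), (1, np.nan, 0, -1), (2, np.nan, 0, -1)]
    edges = [(0.0, 100.0, 1, 0), (0.0, 100.0, 2, 1)]
    sites = [(0, 1.0, "0"), (1, 2.0, "0"), (2, 3.0, "0")]
    muts = [(0, 0, 0, "1", -1), (1, 1, 0, "1", -1), (2, 2, 1, "1", -1)]
    return make_tables(nodes, edges, sites, muts)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated ARG with mutations (session-scoped)."""
    from vgdate.synthcoal import SimConfig, drop_mutations, simulate_arg

    cfg = SimConfig(n_samples=50, sequence_length=2e5, seed=11)
    return drop_mutations(simulate_arg(cfg), cfg.mutation_rate, seed=12), cfg


@pytest.fixture(scope="session")
def diploid_sim():
    """Simulated diploids with singleton mutations stripped of phase."""
    from vgdate.synthcoal import SimConfig, drop_mutations, simulate_arg

    cfg = SimConfig(n_samples=40, ploidy=2, sequence_length=2e5, seed=21)
    return drop_mutations(simulate_arg(cfg), cfg.mutation_rate, seed=22), cfg
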