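import numpy as np
import pandas as pd
import pytest

from medinet.events import DifferentialTable
from medinet.network import DirectedNetwork, insulated_diffusion, row_normalize


def make_network(pairs, kinds=None):
    """Network from (source, target) or (source, target, type) tuples."""
    return DirectedNetwork.from_edge_list(
        [p if len(p) == 3 else (*p, "") for p in pairs], kinds
    )


def diff_table(layer, sample, rows, phospho=False):
    """rows: (feature, log2fc, padj, detected[, gene]) tuples."""
    cols = ["feature", "log2fc", "padj", "detected"]
    if phospho:
        cols.append("gene")
    df = pd.DataFrame(rows, columns=cols)
    return DifferentialTable(layer, sample, df)


@pytest.fixture
def two_cycle():
    return make_network([("A", "B"), ("B", "A")])


@pytest.fixture
def two_cycle_operator(two_cycle):
    return insulated_diffusion(row_normalize(two_cycle), beta=0.5)


def random_digraph(rng, n=50, p=0.12, prefix="N"):
    """Random directed graph as an edge-pair list (no self loops)."""
    adj = rng.random((n, n)) < p
    np.fill_diagonal(adj, False)
    names = [f"{prefix}{k:03d}" for k in range(n)]
    return [(names[i], names[j]) for i, j in zip(*np.nonzero(adj))], names
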