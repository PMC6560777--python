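import numpy as np
import pytest

from pangloss import synthetic as syn
from pangloss.io_core import ClusterTable, TimeTree


@pytest.fixture(scope="session")
def default_config():
    return syn.default_config(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Presence table + truth for the default study conditions."""
    table, truth = syn.simulate_family_evolution(default_config)
    return table, truth


@pytest.fixture(scope="session")
def default_proteomes(default_config, default_dataset):
    table, truth = default_dataset
    return syn.emit_proteomes(table, truth, default_config)


@pytest.fixture
def four_leaf_tree():
    return TimeTree.from_newick_string("((A:10,B:10):5,(C:10,D:10):5):0;")


def table_from_presence(taxa, patterns, prefix="F"):
    """ClusterTable from a taxa x clusters 0/1 (or count) matrix."""
    patterns = np.asarray(patterns)
    members = {}
    for j in range(patterns.shape[1]):
        cid = f"{prefix}{j:03d}"
        mem = []
        for i, t in enumerate(taxa):
            mem.extend((t, f"{cid}_{k}") for k in range(int(patterns[i, j])))
        members[cid] = mem
    return ClusterTable(taxa, list(members), patterns, members)
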