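import numpy as np
import pandas as pd
import pytest

from toxfocus.go_sets import GeneSet
from toxfocus.io_formats import GeneStatTable
from toxfocus.synthetic_data import gen_collection, toy_config


def make_stat_table(rows, condition_id="cond"):
    """Build a GeneStatTable from (gene, log2fc, pvalue) tuples."""
    frame = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    return GeneStatTable(condition_id=condition_id, frame=frame)


def random_gene_sets(rng, n_sets, universe_size=50, max_size=20, prefix="S"):
    universe = [f"g{i}" for i in range(universe_size)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(1, max_size + 1))
        genes = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"{prefix}{i}", f"set {i}", frozenset(genes.tolist())))
    return sets


@pytest.fixture(scope="session")
def toy():
    """The toy-tox collection: (config, pathways, go_sets, truth)."""
    config = toy_config()
    pathways, go_sets, truth = gen_collection(config)
    return config, pathways, go_sets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
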