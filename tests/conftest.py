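import numpy as np
import pandas as pd
import pytest

from methylpath.io import canonical_role, required_roles
from methylpath.simulate import SimulationParams, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared across tests (80 TEs, two 70 kb
    chromosomes, default depth/effect sizes)."""
    params = SimulationParams(seed=11, n_te=80,
                              chrom_sizes={"chr1": 70_000, "chr2": 70_000})
    return simulate(params)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic")
    return small_dataset.write(out)


def classifier_tables(dataset, background):
    """Cytosine tables keyed by canonical classifier role."""
    return {canonical_role(r, background): df
            for r, df in dataset.methylomes[background].items()
            if r in required_roles(background)}


def make_calls(rows):
    """Build a sorted cytosine call table from (chrom, pos, strand, context,
    n_meth, n_total) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "n_meth", "n_total"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
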