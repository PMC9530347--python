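import numpy as np
import pytest

from lcgrn import NormalizedMatrix, PipelineConfig
from lcgrn.pipeline import run_benchmark
from lcgrn.simulate import default_spec


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def benchmark_result():
    """The packaged benchmark (seed 0) run through the whole pipeline once."""
    return run_benchmark(default_spec(seed=0))


def make_norm(values, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from a value array (tests only)."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=values,
        cell_ids=cell_ids or [f"c{i}" for i in range(n_cells)],
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        size_factors=np.ones(n_cells),
    )
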