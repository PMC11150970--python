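import numpy as np
import pandas as pd
import pytest

import myosig as ms


@pytest.fixture(scope="session")
def sc_pair():
    """Derivation + validation synthetic single-cell datasets (default scale)."""
    m, ann, truth = ms.generate_single_cell(ms.default_sc_config(seed=11))
    vm, vann, _ = ms.generate_single_cell(ms.default_sc_config(seed=12))
    return m, ann, truth, vm, vann


@pytest.fixture(scope="session")
def bulk_cohort():
    cfg, truth = ms.default_bulk_config(seed=3)
    m, meta, histo, props = ms.generate_bulk_cohort(cfg)
    return m, meta, histo, props, truth


@pytest.fixture()
def tiny_matrix():
    """4 genes x 6 cells, equal library sizes so normalization is a constant scale."""
    vals = pd.DataFrame(
        [
            [3, 3, 3, 1, 1, 1],   # marker-like: mean 3 in first three cells
            [1, 1, 1, 3, 3, 3],
            [2, 2, 2, 2, 2, 2],
            [4, 4, 4, 4, 4, 4],
        ],
        index=["gA", "gB", "gC", "gD"],
        columns=[f"c{i}" for i in range(6)],
    )
    return ms.CountMatrix(vals, layer="raw_counts")
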