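"""Shared fixtures: the default synthetic dataset and derived objects.

Session-scoped because the dwell simulation + expression sampling + the
bootstrap ranking are the expensive shared substrate of many tests.
"""

import numpy as np
import pytest

from kaede_dcflow.pseudobulk import PseudobulkDesign, bootstrap_rank
from kaede_dcflow.synthetic import (
    DwellModelParams,
    GeneProgram,
    sample_expression,
    simulate_dwell,
)


@pytest.fixture(scope="session")
def dwell_params():
    return DwellModelParams()


@pytest.fixture(scope="session")
def default_cells(dwell_params):
    return simulate_dwell(dwell_params, seed=1)


@pytest.fixture(scope="session")
def default_program():
    return GeneProgram.default(seed=0)


@pytest.fixture(scope="session")
def s23_adata(default_cells, default_program):
    """Expression for tumour DC2/DC3 cells (>= 2000 per state)."""
    cells = default_cells[
        (default_cells["compartment"] == "tumour")
        & (default_cells["state"].isin(["S2_DC2", "S3_DC3"]))
    ]
    adata = sample_expression(cells, default_program, seed=2)
    assert (adata.obs["state"].value_counts() >= 2000).all()
    return adata


@pytest.fixture(scope="session")
def ranked_s23(s23_adata):
    return bootstrap_rank(
        s23_adata, "state", ("S2_DC2", "S3_DC3"), PseudobulkDesign(seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
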