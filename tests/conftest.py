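import numpy as np
import pytest

from stcem import SynthConfig, generate_bundle
from stcem.types import new_cell_table


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(
        seed=7,
        n_cells_st=800,
        n_cells_em=300,
        n_cells_sc=300,
        qc_violator_fraction=0.03,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def medium_bundle():
    """Full-size study conditions, shared across the slower tests."""
    return generate_bundle(SynthConfig(seed=3, n_cells_st=2000, n_cells_em=600))


def make_cells(xy, labels, ids=None):
    xy = np.asarray(xy, dtype=float)
    if ids is None:
        ids = [f"c{i}" for i in range(len(xy))]
    return new_cell_table(ids, xy[:, 0], xy[:, 1], class_label=np.asarray(labels, dtype=object))
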