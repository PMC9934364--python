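"""Shared fixtures: all inputs are generated, none are stored on disk."""

import numpy as np
import pandas as pd
import pytest

from epishape.synthetic import TissueSpec, generate_tissue, make_dataset
from epishape.train_eval import ShapeDataset


@pytest.fixture(scope="session")
def small_dataset():
    """120 synthetic 64x64 tiles (~20 cells each) spanning the target space."""
    spec = TissueSpec(mean_cell_area=200.0, seed=11)
    images, targets = make_dataset(spec, 120, tile_size=64)
    return ShapeDataset(images, targets)


@pytest.fixture(scope="session")
def stretched_tissues():
    """Twenty seeded tissues per stretch factor, with measured shapes."""
    from epishape.ground_truth import window_shape

    out = {}
    for stretch in (1.0, 1.5, 2.0, 2.5):
        rows = []
        for seed in range(20):
            t = generate_tissue(
                TissueSpec(stretch_factor=stretch, alpha0=np.pi / 4, seed=seed)
            )
            st = window_shape(t.labels)
            rows.append(dict(L=st.L, l=st.l, alpha=st.alpha))
        out[stretch] = pd.DataFrame(rows)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
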