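import numpy as np
import pytest

import gcniche as g


@pytest.fixture(scope="session")
def gc_map():
    """A standard simulated GC with moderate T-cell exclusion from the DZ."""
    cellmap, truth = g.simulate_gc_map(g.TissueSimConfig(seed=11))
    return cellmap, truth


@pytest.fixture(scope="session")
def nuclei_fixture():
    """Rendered nuclei (60 DZ / 60 LZ) with features and ground truth."""
    grid = g.grid_cell_map(60, 60, spacing_um=9.0)
    cfg = g.NucleiSimConfig(seed=7)
    img, labels, truth = g.simulate_nuclei_image(grid, cfg)
    feats = g.extract_chrometric_features(img, labels, pixel_size=cfg.pixel_size)
    return grid, img, labels, feats, truth


@pytest.fixture(scope="session")
def labeled_features(nuclei_fixture):
    """Feature matrix + DZ/LZ labels ready for the classifier."""
    grid, _, _, feats, truth = nuclei_fixture
    keep = ~feats["flagged"]
    X = feats.loc[keep, g.FEATURE_NAMES]
    ids = grid.cells["cell_id"].to_numpy()[X.index.to_numpy() - 1]
    X = X.set_axis(ids)
    y = truth.compartment.loc[ids]
    return X, y

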