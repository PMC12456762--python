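import numpy as np
import pandas as pd
import pytest

from maskshaker import (
    FeatureTable,
    LabelMask,
    MultichannelImage,
    TissueSpec,
    calibrate_levels,
    default_gating_tree,
    generate_tissue,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_mask():
    """Two well-separated 4x4 square cells."""
    arr = np.zeros((16, 16), dtype=np.int32)
    arr[2:6, 2:6] = 1
    arr[9:13, 9:13] = 2
    return LabelMask(arr)


@pytest.fixture
def tree():
    return default_gating_tree()


def make_table(values: dict, markers=None) -> FeatureTable:
    """Build a feature table from {cell_id: {col: val}} rows."""
    df = pd.DataFrame.from_dict(values, orient="index")
    df.index.name = "cell_id"
    if markers is None:
        markers = [c for c in df.columns if c not in ("area", "centroid_row", "centroid_col")]
    return FeatureTable(df, markers=markers)


@pytest.fixture(scope="session")
def small_tissue():
    """~200-cell noisy tissue shared by cheap integration tests."""
    spec = TissueSpec(shape=(280, 280), n_cells=200, seed=5)
    return generate_tissue(spec)


@pytest.fixture(scope="session")
def clean_tissue():
    """Noise-free tissue for closed-loop phenotyping checks."""
    spec = TissueSpec(shape=(420, 420), n_cells=600, noise_scale=0.0, seed=3)
    return generate_tissue(spec)


@pytest.fixture(scope="session")
def study_tissue():
    """The ~1,000-cell tissue used for calibration and trend acceptance."""
    spec = TissueSpec(shape=(520, 520), n_cells=1000, seed=7)
    return generate_tissue(spec)


@pytest.fixture(scope="session")
def calibrated_levels(study_tissue):
    """Calibrated perturbation parameters for all four study levels."""
    _, mask, _ = study_tissue
    return calibrate_levels(mask, [100.0, 90.0, 80.0, 70.0], replicates=3, seed=11)
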