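import numpy as np
import pytest

import fieldlift as fl
from fieldlift.training import TrainConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_schedule():
    return fl.build_schedule(T=4, beta_min=0.1, beta_max=20.0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Desk-test training configuration (small widths, 2-level U-Net)."""
    return TrainConfig(base_channels=8, depth=2, z_dim=16, k_adjacent=3,
                       batch_size=2, seed=0)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Two-subject paired phantom dataset on a 48-cube grid."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = fl.make_paired_dataset(2, grid=(48, 48, 48), seed=11, out_dir=out,
                                      lesion_count=1)
    return out, manifest


@pytest.fixture(scope="session")
def t1_pair(dataset_dir):
    from fieldlift.io import load_pair
    _, manifest = dataset_dir
    row = manifest[(manifest.subject_id == "sub-000") & (manifest.contrast == "T1")].iloc[0]
    return load_pair(row)
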