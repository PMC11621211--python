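import numpy as np
import pytest

from gcrtcall.config import ModelConfig, TrainConfig
from gcrtcall.pore_sim import SimConfig, make_pore_model, simulate_dataset
from gcrtcall.training import train


@pytest.fixture(scope="session")
def pore3():
    return make_pore_model(3, seed=7)


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory, pore3):
    """200 noise-free reads, 30-60 bases, geometric dwells: training data."""
    path = tmp_path_factory.mktemp("sim") / "clean.hdf5"
    reads = simulate_dataset(200, (30, 60), pore3,
                             SimConfig(noise_sd_scale=0.0, seed=11), path)
    return path, reads


@pytest.fixture(scope="session")
def heldout_clean_reads(pore3, tmp_path_factory):
    path = tmp_path_factory.mktemp("sim") / "test_clean.hdf5"
    return simulate_dataset(50, (30, 60), pore3,
                            SimConfig(noise_sd_scale=0.0, seed=99), path)


@pytest.fixture(scope="session")
def desk_trained_clean(clean_dataset):
    """The desk-scale training run shared by learnability checks."""
    path, _ = clean_dataset
    return train(ModelConfig.tiny(seed=1), TrainConfig.desk(seed=1), path)


@pytest.fixture(scope="session")
def overfit_model(tmp_path_factory):
    """A micro model driven to convergence on 12 dispersion-free reads.

    Noise-free, constant-dwell squiggles are exactly decodable, so a small
    network trained long enough recovers every training read perfectly;
    several end-to-end exactness tests share this fixture.
    """
    pore = make_pore_model(3, seed=5)
    sim = SimConfig(noise_sd_scale=0.0, dwell_dispersion=0.0, seed=21,
                    translocation_speed=75.3)
    path = tmp_path_factory.mktemp("sim") / "overfit.hdf5"
    reads = simulate_dataset(12, (30, 45), pore, sim, path)
    cfg = ModelConfig.tiny(seed=0, d_model=32, n_blocks=1, n_heads=2,
                           frontend_channels=(8, 16, 32))
    tcfg = TrainConfig.desk(seed=0, epochs=25, learning_rate=0.008,
                            epoch_lr_scale=0.92, chunk_stride=64,
                            val_fraction=0.0, swa=False)
    result = train(cfg, tcfg, path)
    return result.model, reads, pore, sim
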