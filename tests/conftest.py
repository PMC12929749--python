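import numpy as np
import pytest

from rpeseg.core import BinaryMask3D, ImageVolume
from rpeseg.experiment import ExperimentConfig, run_experiment
from rpeseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def easy_case():
    """One deterministic high-contrast phantom used across test modules."""
    return generate_phantom(PhantomSpec(seed=11, lesion_contrast=3.0))


@pytest.fixture
def small_volume():
    rng = np.random.default_rng(0)
    data = rng.random((8, 16, 16)).astype(np.float32)
    return ImageVolume(id="v0", data=data, spacing=(4.8, 0.5, 0.5))


@pytest.fixture
def small_mask(small_volume):
    data = np.zeros(small_volume.shape, dtype=np.uint8)
    data[3:5, 6:10, 7:12] = 1
    return BinaryMask3D(data=data, spacing=small_volume.spacing)


def mini_config(seed: int = 7) -> ExperimentConfig:
    """A minutes-scale configuration for orchestration-level tests."""
    return ExperimentConfig(
        n_phantoms=6, n_folds=2, clf_epochs=1, unet_epochs=2,
        max_train_slices=60, max_train_tiles=24, youden_max_patients=2,
        tile_patients_max=2, seed=seed)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One tiny end-to-end cross-validated run, shared across tests."""
    outdir = tmp_path_factory.mktemp("mini_run")
    return run_experiment(mini_config(), outdir), outdir
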