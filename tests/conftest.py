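import numpy as np
import pytest

from pdnn.network import ArchConfig
from pdnn.stimuli import GlyphSource, build_dataset

# micro architecture for fast unit tests (not the desk analysis profile)
TINY_ARCH = ArchConfig(width_scale=1 / 32, bottleneck_scale=1, recurrence=(1, 1, 1, 1))

# desk analysis profile shared by the acceptance suite
DESK_ARCH = ArchConfig(width_scale=1 / 16, bottleneck_scale=2, recurrence=(1, 2, 2, 2))


@pytest.fixture(scope="session")
def tiny_source():
    return GlyphSource.synthetic("train", pool_size=4, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_source):
    return build_dataset(2, tiny_source, tiny_source, seed=7)


@pytest.fixture(scope="session")
def desk_dataset():
    """Reduced-scale stimulus set: 20 variants per problem, shared glyph pool."""
    source = GlyphSource.synthetic("train", pool_size=12, seed=1)
    return build_dataset(20, source, source, seed=1)


@pytest.fixture(scope="session")
def suite_sweep(desk_dataset, tmp_path_factory):
    """The shared 17-gain excitability sweep used by the acceptance suite.

    Short-horizon training (300 iterations per gain) at the desk scale;
    checkpoints are stored so representational analyses can reload
    networks at evaluated iterations.
    """
    from pdnn.network import gain_grid
    from pdnn.training import TrainConfig, sweep_gains

    ckpt = tmp_path_factory.mktemp("sweep_ckpt")
    cfg = TrainConfig(batch_size=50, learning_rate=3e-3, eval_every=50,
                      max_iterations=300, seed=1, eval_subsample=380,
                      keep_responses=True, checkpoint_dir=str(ckpt))
    return sweep_gains(desk_dataset, gain_grid(), DESK_ARCH, cfg)
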