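import numpy as np
import pytest

import brainseg as bs
from brainseg import cnn as C
from brainseg.pipeline import PipelineConfig, run_all


@pytest.fixture(scope="session")
def zero_noise_pair():
    """One clean phantom slice (no facial clutter): intensities exactly in-band."""
    return bs.generate_phantom(
        bs.PhantomSpec(noise_sigma=0, facial_structures=False, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_pair():
    """One sigma=5 slice with facial clutter, plus its clean counterpart."""
    clean = bs.generate_phantom(
        bs.PhantomSpec(noise_sigma=0, facial_structures=True, seed=3)
    )
    noisy = bs.generate_phantom(
        bs.PhantomSpec(noise_sigma=5, facial_structures=True, seed=3)
    )
    return clean, noisy


@pytest.fixture(scope="session")
def trained_lenet():
    """LeNet-variant classifier trained on clean phantom patches.

    Classes are separable by centre intensity alone, so the network should
    approach the range-threshold oracle; shared across the CNN tests.
    """
    spec = bs.PhantomSpec(noise_sigma=0, facial_structures=False, seed=123)
    pairs = bs.generate_dataset(spec, 1, 6)
    sets = []
    for i, p in enumerate(pairs):
        sup = bs.suppress_out_of_range(p.image)
        sets.append(C.extract_patches(sup, p.truth, 32, stride=7, image_id=i))
    patches = C.merge_patchsets(sets)
    cfg = C.TrainConfig(epochs=16, subepochs_per_epoch=20, batch_size=2,
                        patches_per_image=60, split=(4, 2, 0), seed=0)
    model = C.build_model(C.CnnSpec("LENET"), seed=0)
    result = C.train(model, patches, cfg)
    return result, patches, cfg


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full default pipeline (1 subject x 16 slices, sigma=5, seed 1)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=1, out_dir=str(out))
    report = run_all(cfg)
    return cfg, report
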