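import numpy as np
import pytest

from sonotx.synthetic import StudyConfig, generate_study


def random_masked_image(rng, size=8, ng=4, full_mask=False):
    """Random quantization-ready test image with a random (or full) mask."""
    img = rng.uniform(0, 255, size=(size, size))
    if full_mask:
        mask = np.ones((size, size), dtype=bool)
    else:
        mask = rng.random((size, size)) < 0.8
        if not mask.any():
            mask[size // 2, size // 2] = True
    return img, mask


@pytest.fixture(scope="session")
def small_study():
    """One small seeded study reused by read-only tests."""
    cfg = StudyConfig(n_healthy=6, n_T2c=8, n_T3b=6, image_size=64,
                      n_mrna=250, n_mirna=90, n_planted_de=10, seed=11)
    return generate_study(cfg)
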