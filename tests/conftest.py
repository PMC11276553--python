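import numpy as np
import pytest

from cccm import EmbeddingConfig, cross_map, generate, preset_spec


@pytest.fixture(scope="session")
def cfg51():
    return EmbeddingConfig(E=5, tau=1)


@pytest.fixture(scope="session")
def cfg55():
    return EmbeddingConfig(E=5, tau=5)


def multiseed_rho(preset, config, n_seeds=20, direction="xy", mode="cccm",
                  n=None, noise=None, transform=None):
    """Mean/spread of cross-map skill over independent generator seeds."""
    rhos = []
    for seed in range(n_seeds):
        x, y = generate(preset_spec(preset, n=n, seed=seed, noise=noise))[:2]
        if transform is not None:
            x, y = transform(x), transform(y)
        src, tgt = (x, y) if direction == "xy" else (y, x)
        rhos.append(cross_map(src, tgt, config, mode=mode).rho)
    rhos = np.asarray(rhos)
    return float(rhos.mean()), rhos
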