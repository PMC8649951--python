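import numpy as np
import pytest

from t1moco import moconet, phantom, training


@pytest.fixture(scope="session")
def default_phantom():
    return phantom.make_phantom(shape=(64, 64), seed=0)


@pytest.fixture(scope="session")
def clean_stack(default_phantom):
    return phantom.simulate_irw(default_phantom, noise_sigma=0.0)


def make_clean_stacks(n, base_seed=0, shape=(64, 64), noise_sigma=1.0, blur_sigma_px=1.0):
    rng = np.random.default_rng(base_seed)
    scale = min(shape) / 64.0
    stacks = []
    for _ in range(n):
        s = int(rng.integers(2**31))
        tm = phantom.make_phantom(
            shape=shape, r_inner=8.0 * scale, r_outer=14.0 * scale,
            jitter_px=2.0 * scale, seed=s,
        )
        stacks.append(
            phantom.simulate_irw(tm, noise_sigma=noise_sigma, seed=s + 1,
                                 blur_sigma_px=blur_sigma_px)
        )
    return stacks


@pytest.fixture(scope="session")
def desk_model():
    """A small model trained at desk scale; shared by the slower end-to-end
    tests so the expensive training run happens once per session."""
    stacks = make_clean_stacks(200, base_seed=123, blur_sigma_px=0.0)
    model = moconet.build_network(moconet.NetworkConfig(base_channels=6), seed=7)
    cfg = training.TrainConfig(
        max_epochs=12, patience_epochs=12, pad_size=(64, 64),
        amplitude_px=3.0, smoothness_px=8.0, seed=7,
    )
    model, history = training.train(model, stacks, cfg)
    return model, history
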