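import numpy as np
import pytest

from octcvd.phantom import PhantomConfig, default_layers, generate_bscan, measure_band_thickness
from octcvd.vae import ConvVAE, VaeConfig, train_vae


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    return PhantomConfig(
        image_height=64, image_width=64, n_bscans=4, speckle_level=0.1,
        undulation_amp=1.0,
    )


@pytest.fixture(scope="session")
def choroid_phantoms():
    """Phantom B-scans whose only systematic variation is choroid thickness.

    Returns (images, boundary_maps, mean_choroid_thickness_per_image).
    """
    config = PhantomConfig(
        image_height=64, image_width=64, n_bscans=1, speckle_level=0.1,
        undulation_amp=1.5,
    )
    layers = default_layers(64)
    rng = np.random.default_rng(3)
    imgs, maps, ths = [], [], []
    for _ in range(400):
        scale = float(np.exp(0.25 * rng.standard_normal()))
        img, bmap = generate_bscan(
            layers, config, rng, thickness_scales={"CHOROID_LOWER": scale}
        )
        imgs.append(img)
        maps.append(bmap)
        ths.append(measure_band_thickness(bmap).mean())
    return np.stack(imgs), np.stack(maps), np.array(ths)


@pytest.fixture(scope="session")
def choroid_vae(choroid_phantoms):
    """A small VAE trained on the choroid-varying phantoms (shared across
    representation-learning and explainability tests)."""
    imgs, _, _ = choroid_phantoms
    config = VaeConfig(
        latent_dim=16, conv_layers=4, base_channels=8, image_size=64,
        epochs=20, anneal_epochs=5, batch_size=32, seed=0,
    )
    model, history = train_vae(imgs, config)
    return model, history
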