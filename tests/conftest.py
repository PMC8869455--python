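"""Shared fixtures: phantom datasets and trained desk-scale models.

Heavy fixtures are session-scoped so the VAE, GAN, and auxiliary scorer
are each trained once and reused by unit, property, and acceptance
tests.  All randomness is seeded; the suite is deterministic.
"""

import numpy as np
import pytest
from scipy import ndimage

from edgan import (
    ConditionalGAN,
    PhantomVAE,
    ResidualClassifier,
    generate_dataset,
    noise_source,
)

SIDE = 32
LATENT = 16


@pytest.fixture(scope="session")
def desk_train():
    """60 phantoms per class at side 32 — the main training fixture."""
    return generate_dataset(60, side=SIDE, seed=0)


@pytest.fixture(scope="session")
def desk_test():
    """Held-out phantoms drawn from an independent seed."""
    return generate_dataset(40, side=SIDE, seed=999)


@pytest.fixture(scope="session")
def fixture_vae(desk_train):
    """VAE trained on the desk fixture (60 epochs, Adam)."""
    vae = PhantomVAE(side=SIDE, latent_dim=LATENT, epochs=60,
                     learning_rate=2e-3, random_state=0)
    return vae.fit(desk_train.images())


@pytest.fixture(scope="session")
def scorer():
    """Auxiliary phantom classifier used to score generated images.

    Trained on crisp phantoms plus Gaussian-blurred copies so it stays
    calibrated on the smoother images a desk-scale generator emits.
    """
    ds = generate_dataset(200, side=SIDE, seed=10)
    X, y = ds.images(), ds.label_indices()
    rng = np.random.default_rng(3)
    Xb = np.stack([ndimage.gaussian_filter(im, rng.uniform(0.5, 1.8)) for im in X])
    clf = ResidualClassifier(side=SIDE, epochs=6, learning_rate=2e-3,
                             batch_size=50, random_state=0)
    return clf.fit(np.concatenate([X, Xb]), np.concatenate([y, y]))


@pytest.fixture(scope="session")
def fixture_gan(desk_train, fixture_vae):
    """Conditional GAN trained on informative noise (desk fixture run)."""
    gan = ConditionalGAN(side=SIDE, latent_dim=LATENT, gen_hidden=256,
                         disc_hidden=256, steps=1500, batch_size=32,
                         random_state=0)
    stream = noise_source(fixture_vae, "informative", rng=123)
    return gan.fit(desk_train, noise=stream)
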