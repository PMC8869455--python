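"""Class-conditional GAN seeded by informative noise.

Two builder families are provided:

* full-scale declarative specs matching the published 256x256
  architecture exactly (generator: dense 100 -> 1,310,720, reshape to
  32x32x1280, three stride-2 transposed convolutions with 1280 filters
  and kernel 4, final kernel-32 convolution to one channel —
  212,340,481 parameters; discriminator: three stride-2 convolutions
  128/64/32 with kernel 3, dropout, dense to one unit — 126,305
  parameters).  These are used for architecture verification, not CPU
  training.
* a desk-scale trainable variant.  The adversarial pair trained on CPU
  uses multi-layer perceptrons (an admissible GAN parameterization) so
  the mode-collapse and augmentation experiments run in seconds.

Conditioning follows the auxiliary-label recipe: the generator receives
the one-hot class label concatenated to its noise vector, the
discriminator a constant label channel map concatenated to the image.
The generator is trained with the non-saturating loss (maximize
log D(G(z|c)|c)); the discriminator with standard cross-entropy on
real/fake.
"""

from __future__ import annotations

import csv
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .phantoms import CLASS_NAMES, ImageSample, LabeledDataset
from .swap import NoiseStream

__all__ = [
    "build_generator",
    "build_discriminator",
    "gan_value",
    "generator_input",
    "discriminator_input",
    "conditional_forward",
    "ConditionalGAN",
    "write_gan_log",
]

#: width divisor and side used by the desk-scale conv builders
DESK_SIDE = 64
DESK_WIDTH_FACTOR = 16


def build_generator(scale: str = "full", conditional: bool = False,
                    n_classes: int = 3, latent_dim: int = 100,
                    final_kernel: Optional[int] = None) -> nn.NetworkSpec:
    """Generator NetworkSpec.

    ``full`` (alias ``paper``) reproduces the published parameter table
    exactly (in its unconditional form; ``conditional`` widens the input
    by the one-hot label).  ``desk`` keeps the topology at side 64 with
    channel widths cut by 16.  ``final_kernel`` overrides the unusual
    kernel-32 output convolution (e.g. 3 for a conventional head) — the
    published parameter count holds only for 32.
    """
    if scale in ("full", "paper"):
        side, ch = 256, 1280
        fk = 32 if final_kernel is None else final_kernel
    elif scale == "desk":
        side, ch = DESK_SIDE, 1280 // DESK_WIDTH_FACTOR
        fk = 9 if final_kernel is None else final_kernel
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'full' or 'desk'")
    base = side // 8
    d_in = latent_dim + (n_classes if conditional else 0)
    layers = [
        nn.dense(base * base * ch),
        nn.leaky_relu(0.2),
        nn.reshape((base, base, ch)),
    ]
    for _ in range(3):
        layers += [nn.conv2d_transpose(ch, kernel=4, stride=2), nn.leaky_relu(0.2)]
    layers += [nn.conv2d(1, kernel=fk, stride=1), nn.sigmoid()]
    return nn.NetworkSpec((d_in,), layers, name=f"generator-{scale}")


def build_discriminator(scale: str = "full", conditional: bool = False,
                        dropout_rate: float = 0.3) -> nn.NetworkSpec:
    """Discriminator NetworkSpec (sigmoid head, output in (0,1))."""
    if scale in ("full", "paper"):
        side, widths = 256, (128, 64, 32)
    elif scale == "desk":
        side = DESK_SIDE
        widths = tuple(w // DESK_WIDTH_FACTOR for w in (128, 64, 32))
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'full' or 'desk'")
    channels = 2 if conditional else 1
    layers = []
    for w in widths:
        layers += [nn.conv2d(w, kernel=3, stride=2), nn.leaky_relu(0.2)]
    layers += [nn.dropout(dropout_rate), nn.flatten(), nn.dense(1), nn.sigmoid()]
    return nn.NetworkSpec((side, side, channels), layers, name=f"discriminator-{scale}")


def gan_value(d_real, d_fake) -> float:
    """Min-max value function: E[log D(x)] + E[log(1 - D(G(z)))]."""
    d_real = np.atleast_1d(np.asarray(d_real, dtype=np.float64))
    d_fake = np.atleast_1d(np.asarray(d_fake, dtype=np.float64))
    for name, p in (("d_real", d_real), ("d_fake", d_fake)):
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError(f"{name} probabilities must lie strictly in (0, 1)")
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def generator_input(z: np.ndarray, labels, n_classes: int = 3) -> np.ndarray:
    """One-hot label concatenated to each noise vector."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    labels = np.broadcast_to(np.asarray(labels, dtype=np.int64), (z.shape[0],))
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    onehot = np.eye(n_classes)[labels]
    return np.concatenate([z, onehot], axis=1)


def discriminator_input(images: np.ndarray, labels, n_classes: int = 3) -> np.ndarray:
    """Constant label channel map concatenated to the image: (n, h, w, 2)."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    n, h, w = images.shape
    labels = np.broadcast_to(np.asarray(labels, dtype=np.int64), (n,))
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    level = labels / max(n_classes - 1, 1)
    label_map = np.broadcast_to(level[:, None, None], (n, h, w))
    return np.stack([images, label_map], axis=-1)


def conditional_forward(net: nn.Network, inputs: np.ndarray, label,
                        n_classes: int = 3) -> np.ndarray:
    """Forward pass with the label wired in as auxiliary input.

    Noise inputs (2-D) take the generator route (one-hot concat); image
    inputs (3-D) the discriminator route (label channel map).  Flat-input
    networks receive flattened conditioned inputs.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim <= 2:
        x = generator_input(inputs, label, n_classes)
    else:
        x = discriminator_input(inputs, label, n_classes)
    if len(net.spec.input_shape) == 1 and x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    return net.forward(x)


class ConditionalGAN(BaseEstimator):
    """Desk-scale trainable conditional GAN (MLP generator/discriminator).

    ``fit(X, y, noise=...)`` trains with alternating single D and G steps
    on minibatches; ``noise`` is a :class:`edgan.swap.NoiseStream`
    (informative or gaussian; defaults to gaussian at ``latent_dim``).
    ``generate(label, n)`` emits labeled images in [0, 1].

    Fitted attributes: ``generator_``, ``discriminator_`` (logit head),
    ``train_log_`` (per-step d_loss/g_loss/d_real/d_fake).
    """

    def __init__(self, side: int = 32, latent_dim: int = 16, n_classes: int = 3,
                 gen_hidden: int = 128, disc_hidden: int = 128,
                 steps: int = 400, batch_size: int = 32,
                 learning_rate: float = 2e-4, beta1: float = 0.5,
                 label_mismatch: bool = True, label_scale: float = 1.0,
                 random_state: int = 0):
        self.side = side
        self.latent_dim = latent_dim
        self.n_classes = n_classes
        self.gen_hidden = gen_hidden
        self.disc_hidden = disc_hidden
        self.steps = steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.label_mismatch = label_mismatch
        self.label_scale = label_scale
        self.random_state = random_state

    def _gen_input(self, z, labels):
        x = generator_input(z, labels, self.n_classes)
        if self.label_scale != 1.0:
            x = x.copy()
            x[:, self.latent_dim:] *= self.label_scale
        return x

    def generator_spec(self) -> nn.NetworkSpec:
        return nn.NetworkSpec(
            (self.latent_dim + self.n_classes,),
            [nn.dense(self.gen_hidden), nn.leaky_relu(0.2),
             nn.dense(self.side * self.side), nn.sigmoid()],
            name="generator-mlp",
        )

    #: per-class width of the repeated one-hot label block fed to the MLP
    #: discriminator (orthogonal label directions train much faster than a
    #: single graded label level)
    _LABEL_REPEAT = 32

    def discriminator_spec(self) -> nn.NetworkSpec:
        # logit head: sigmoid folded into the loss for numerical stability
        return nn.NetworkSpec(
            (self.side * self.side + self.n_classes * self._LABEL_REPEAT,),
            [nn.dense(self.disc_hidden), nn.leaky_relu(0.2), nn.dense(1)],
            name="discriminator-mlp",
        )

    # -- helpers -----------------------------------------------------------

    def _coerce(self, X, y):
        if isinstance(X, LabeledDataset):
            return X.images(), X.label_indices(), X.class_names
        X = np.asarray(X, dtype=np.float64)
        if y is None:
            raise ValueError("y labels required when X is a raw array")
        return X, np.asarray(y, dtype=np.int64), CLASS_NAMES

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None, noise: Optional[NoiseStream] = None) -> "ConditionalGAN":
        images, labels, self.class_names_ = self._coerce(X, y)
        n = images.shape[0]
        if n == 0:
            raise ValueError("cannot train a GAN on an empty dataset")
        if images.shape[1] != self.side:
            raise ValueError(f"expected side {self.side}, got {images.shape[1:]}")
        rng = np.random.default_rng(self.random_state)
        if noise is None:
            noise = NoiseStream(self.latent_dim, mode="gaussian",
                                rng=np.random.default_rng(self.random_state + 1))
        if noise.dim != self.latent_dim:
            raise ValueError(f"noise stream dim {noise.dim} != latent_dim {self.latent_dim}")
        self.generator_ = self.generator_spec().build(rng)
        self.discriminator_ = self.discriminator_spec().build(rng)
        g_opt = nn.Adam(self.generator_.params, lr=self.learning_rate, beta1=self.beta1)
        d_opt = nn.Adam(self.discriminator_.params, lr=self.learning_rate, beta1=self.beta1)
        flat_real_all = images.reshape(n, -1)
        self.train_log_ = []
        b = min(self.batch_size, n)
        for step in range(self.steps):
            # --- discriminator step
            idx = rng.choice(n, size=b, replace=False)
            real_flat = np.concatenate(
                [flat_real_all[idx],
                 self._label_map_flat(labels[idx])], axis=1)
            fake_labels = rng.integers(0, self.n_classes, size=b)
            z = noise.next_batch(b)
            fake_imgs = self.generator_.forward(self._gen_input(z, fake_labels))
            fake_flat = np.concatenate([fake_imgs, self._label_map_flat(fake_labels)], axis=1)
            parts, targets = [real_flat, fake_flat], [np.ones(b), np.zeros(b)]
            if self.label_mismatch:
                # real images paired with wrong labels count as fakes, which
                # is what forces D (and hence G) to respect the condition
                shift = rng.integers(1, self.n_classes, size=b)
                wrong = (labels[idx] + shift) % self.n_classes
                parts.append(np.concatenate([flat_real_all[idx],
                                             self._label_map_flat(wrong)], axis=1))
                targets.append(np.zeros(b))
            d_in = np.concatenate(parts, axis=0)
            target = np.concatenate(targets)[:, None]
            logits = self.discriminator_.forward(d_in, train=True, rng=rng)
            p = self._sigmoid(logits)
            d_loss = float(-(target * np.log(np.clip(p, 1e-12, 1)) +
                             (1 - target) * np.log(np.clip(1 - p, 1e-12, 1))).mean())
            self.discriminator_.backward((p - target) / len(d_in))
            d_opt.step(self.discriminator_.grads)
            d_real_mean = float(p[:b].mean())
            d_fake_mean = float(p[b:].mean())

            # --- generator step (non-saturating loss)
            g_labels = rng.integers(0, self.n_classes, size=b)
            z = noise.next_batch(b)
            g_in = self._gen_input(z, g_labels)
            imgs = self.generator_.forward(g_in, train=True, rng=rng)
            gd_in = np.concatenate([imgs, self._label_map_flat(g_labels)], axis=1)
            logits = self.discriminator_.forward(gd_in)
            p = self._sigmoid(logits)
            g_loss = float(-np.log(np.clip(p, 1e-12, 1)).mean())
            d_grad_in = self.discriminator_.backward((p - 1.0) / b)
            self.generator_.backward(d_grad_in[:, : self.side * self.side])
            g_opt.step(self.generator_.grads)

            self.train_log_.append({
                "step": step + 1, "d_loss": d_loss, "g_loss": g_loss,
                "d_real": d_real_mean, "d_fake": d_fake_mean,
            })
        return self

    def _label_map_flat(self, labels):
        onehot = np.eye(self.n_classes)[np.asarray(labels, dtype=np.int64)]
        return np.repeat(onehot, self._LABEL_REPEAT, axis=1)

    # -- sampling ----------------------------------------------------------

    def generate(self, label: int, n: int, noise: Optional[NoiseStream] = None,
                 rng=None) -> LabeledDataset:
        """``n`` images of the requested class as a :class:`LabeledDataset`."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if not 0 <= int(label) < self.n_classes:
            raise ValueError(f"label {label} out of range")
        if noise is None:
            z = np.random.default_rng(rng).standard_normal((n, self.latent_dim))
        else:
            z = noise.next_batch(n)
        imgs = self.generator_.forward(self._gen_input(z, int(label)))
        imgs = np.clip(imgs.reshape(n, self.side, self.side), 0.0, 1.0)
        name = self.class_names_[int(label)] if hasattr(self, "class_names_") else CLASS_NAMES[int(label)]
        samples = [ImageSample(img, name) for img in imgs]
        return LabeledDataset(samples, tuple(getattr(self, "class_names_", CLASS_NAMES)))

    def generate_images(self, labels, noise: Optional[NoiseStream] = None, rng=None):
        """Array form: images (n, side, side) for a vector of label indices."""
        labels = np.asarray(labels, dtype=np.int64)
        if noise is None:
            z = np.random.default_rng(rng).standard_normal((len(labels), self.latent_dim))
        else:
            z = noise.next_batch(len(labels))
        imgs = self.generator_.forward(self._gen_input(z, labels))
        return np.clip(imgs.reshape(len(labels), self.side, self.side), 0.0, 1.0)


def write_gan_log(log, path) -> None:
    cols = ["step", "d_loss", "g_loss", "d_real", "d_fake"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerows(log)
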