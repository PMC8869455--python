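"""Variational autoencoder on phantom slices.

The encoder maps an image x to the parameters (mu, log sigma^2) of an
approximate Gaussian posterior q(z|x); the decoder maps latent vectors
back to pixel space.  Training minimizes the negative evidence lower
bound: a reconstruction negative log-likelihood (pixel-wise Bernoulli
cross-entropy by default, Gaussian/MSE optionally) plus the closed-form
KL divergence from q(z|x) to the standard-normal prior,

    KL = -1/2 * sum_i (1 + log_var_i - mu_i^2 - exp(log_var_i)).

The trained encoder/decoder pair is the ingredient the decoder-encoder
swap (:mod:`edgan.swap`) turns into an informative-noise source.
"""

from __future__ import annotations

import csv
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import nn

__all__ = ["PhantomVAE", "elbo_loss", "write_train_log"]


def elbo_loss(x: np.ndarray, x_recon: np.ndarray, mu: np.ndarray,
              log_var: np.ndarray, likelihood: str = "bernoulli"):
    """Negative-ELBO terms: (total, recon_term, kl_term).

    ``x``/``x_recon`` may be single images or batches; terms are summed
    over pixels/latent coordinates and averaged over the batch.  The
    reconstruction term is the negative log-likelihood of ``x`` under a
    pixel-wise Bernoulli with mean ``x_recon`` (or squared error for
    ``likelihood='mse'``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    x_recon = np.atleast_2d(np.asarray(x_recon, dtype=np.float64))
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    log_var = np.atleast_2d(np.asarray(log_var, dtype=np.float64))
    if x.shape != x_recon.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs x_recon {x_recon.shape}")
    if mu.shape != log_var.shape:
        raise ValueError(f"shape mismatch: mu {mu.shape} vs log_var {log_var.shape}")
    b = x.shape[0]
    xf = x.reshape(b, -1)
    rf = np.clip(x_recon.reshape(b, -1), 1e-12, 1.0 - 1e-12)
    if likelihood == "bernoulli":
        recon = -(xf * np.log(rf) + (1.0 - xf) * np.log(1.0 - rf)).sum(axis=1)
    elif likelihood == "mse":
        recon = ((xf - rf) ** 2).sum(axis=1)
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")
    kl = -0.5 * (1.0 + log_var - mu**2 - np.exp(log_var)).sum(axis=1)
    recon_term = float(recon.mean())
    kl_term = float(kl.mean())
    return recon_term + kl_term, recon_term, kl_term


class PhantomVAE(BaseEstimator):
    """Sklearn-style VAE estimator over square grayscale images.

    Parameters
    ----------
    side : image side (power of two).
    latent_dim : dimension d of the latent space.
    hidden : width of the single hidden layer of the MLP encoder/decoder.
    likelihood : 'bernoulli' (cross-entropy) or 'mse'.
    log_var_clip : numerical-safety bounds on the encoder's log-variance.
    epochs, batch_size, learning_rate : Adam minibatch training settings.
    random_state : seed controlling init, shuffling, and reparameterization.

    Fitted attributes: ``encoder_``, ``decoder_`` (:class:`edgan.nn.Network`,
    decoder emits logits), ``train_log_`` (list of per-epoch dicts with
    ``total``/``recon``/``kl``).
    """

    def __init__(self, side: int = 32, latent_dim: int = 16, hidden: int = 256,
                 likelihood: str = "bernoulli", log_var_clip: Tuple[float, float] = (-10.0, 10.0),
                 epochs: int = 20, batch_size: int = 32, learning_rate: float = 1e-4,
                 random_state: int = 0):
        self.side = side
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.likelihood = likelihood
        self.log_var_clip = log_var_clip
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- architecture ------------------------------------------------------

    def encoder_spec(self) -> nn.NetworkSpec:
        return nn.NetworkSpec(
            (self.side * self.side,),
            [nn.dense(self.hidden), nn.leaky_relu(0.2), nn.dense(2 * self.latent_dim)],
            name="vae-encoder",
        )

    def decoder_spec(self) -> nn.NetworkSpec:
        # final sigmoid is applied outside the network so training can use
        # the numerically stable logit-space cross-entropy gradient
        return nn.NetworkSpec(
            (self.latent_dim,),
            [nn.dense(self.hidden), nn.leaky_relu(0.2), nn.dense(self.side * self.side)],
            name="vae-decoder",
        )

    def _init_networks(self, rng: np.random.Generator) -> None:
        self.encoder_ = self.encoder_spec().build(rng)
        self.decoder_ = self.decoder_spec().build(rng)

    # -- inference ---------------------------------------------------------

    def _as_batch(self, X) -> np.ndarray:
        X = np.asarray(getattr(X, "pixels", X), dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.side or X.shape[2] != self.side:
            raise ValueError(f"expected images of side {self.side}, got shape {X.shape}")
        return X.reshape(X.shape[0], self.side * self.side)

    def encode(self, X) -> Tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, log_var), each (n, latent_dim)."""
        flat = self._as_batch(X)
        out = self.encoder_.forward(flat)
        mu, log_var = out[:, : self.latent_dim], out[:, self.latent_dim:]
        return mu, np.clip(log_var, *self.log_var_clip)

    def reparameterize(self, mu: np.ndarray, log_var: np.ndarray, rng=None) -> np.ndarray:
        """z = mu + exp(log_var / 2) * eps, eps ~ N(0, I)."""
        rng = np.random.default_rng(rng)
        eps = rng.standard_normal(np.shape(mu))
        return np.asarray(mu) + np.exp(np.asarray(log_var) / 2.0) * eps

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Latent vectors to images in [0,1], shape (n, side, side)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"latent length {z.shape[1]} != d={self.latent_dim}")
        logits = self.decoder_.forward(z)
        img = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        return img.reshape(z.shape[0], self.side, self.side)

    def reconstruct(self, X) -> np.ndarray:
        """Deterministic posterior-mean round trip decode(encode_mu(x))."""
        mu, _ = self.encode(X)
        return self.decode(mu)

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None) -> "PhantomVAE":
        """Minibatch Adam training of the negative ELBO."""
        flat = self._as_batch(X)
        n = flat.shape[0]
        if n == 0:
            raise ValueError("cannot train a VAE on an empty dataset")
        rng = np.random.default_rng(self.random_state)
        self._init_networks(rng)
        opt = nn.Adam(self.encoder_.params + self.decoder_.params, lr=self.learning_rate)
        self.train_log_ = []
        d = self.latent_dim
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            tot = rec = kld = 0.0
            n_batches = 0
            for lo in range(0, n, self.batch_size):
                xb = flat[order[lo: lo + self.batch_size]]
                b = xb.shape[0]
                out = self.encoder_.forward(xb)
                mu, log_var = out[:, :d], np.clip(out[:, d:], *self.log_var_clip)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(log_var / 2.0)
                z = mu + std * eps
                logits = self.decoder_.forward(z)
                p = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
                if self.likelihood == "bernoulli":
                    rec_b = -(xb * np.log(np.clip(p, 1e-12, 1)) +
                              (1 - xb) * np.log(np.clip(1 - p, 1e-12, 1))).sum(axis=1).mean()
                    dlogits = (p - xb) / b
                else:
                    rec_b = ((p - xb) ** 2).sum(axis=1).mean()
                    dlogits = 2.0 * (p - xb) * p * (1.0 - p) / b
                kl_b = -0.5 * (1 + log_var - mu**2 - np.exp(log_var)).sum(axis=1).mean()
                dz = self.decoder_.backward(dlogits)
                dmu = dz + mu / b
                dlogvar = dz * eps * 0.5 * std + 0.5 * (np.exp(log_var) - 1.0) / b
                self.encoder_.backward(np.concatenate([dmu, dlogvar], axis=1))
                opt.step(self.encoder_.grads + self.decoder_.grads)
                tot += rec_b + kl_b
                rec += rec_b
                kld += kl_b
                n_batches += 1
            self.train_log_.append({
                "epoch": epoch + 1,
                "total": tot / n_batches,
                "recon": rec / n_batches,
                "kl": kld / n_batches,
            })
        return self


def write_train_log(log, path) -> None:
    """Per-epoch loss records to CSV."""
    if not log:
        cols = ["epoch", "total", "recon", "kl"]
    else:
        cols = list(log[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        w.writerows(log)
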